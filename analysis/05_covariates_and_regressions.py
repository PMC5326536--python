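#!/usr/bin/env python
"""Explain windowed diversity with genomic covariates.

Builds the per-window predictor table (recombination rate, CDS density,
weighted dS, intergenic GC, repeat density, chromosome length), then runs
the full statistical battery: cross-species Spearman correlation with and
without coding sequence masked, the chromosome-length covariate model, the
five-predictor OLS, principal component regression, and the decile-stratified
diversity ~ recombination fits. Writes results/covariates_a.tsv and
results/regressions.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from synpi import intervals as iv
from synpi.covariates import build_covariate_table
from synpi.diversity import apply_window_qc, compute_windowed_pi
from synpi.io import (read_bed, read_chrom_sizes, read_gff_features,
                      read_tsv_covariate, write_tsv)
from synpi.regress import (chromosome_covariate_model,
                           decile_stratified_regression, ols, pcr, spearman)

SIM_DIR = Path("scratch/sim/default")
PREDICTORS = ["rec_log10", "cds_sqrt", "gc", "ds_sqrt", "repeat_density"]


def masked_species_pi(species, windows, cds):
    mask = iv.track_from_frame(cds)
    tables = []
    for pop in ("pop1", "pop2"):
        acc = read_tsv_covariate(SIM_DIR / f"accessible_{species}.{pop}.tsv",
                                 ["window_id"], "n_sites")
        tables.append(compute_windowed_pi(SIM_DIR / f"{species}.{pop}.vcf",
                                          windows, pop, accessible=acc, mask=mask))
    qc = apply_window_qc(tables)
    kept = qc[qc["qc_verdict"] == "kept"]
    return kept[["window_id", "pi_species"]].rename(columns={"pi_species": f"pi_{species}"})


def main():
    wmap = pd.read_csv("results/window_map.tsv", sep="\t")
    retained = wmap[wmap["verdict"] == "retained"]
    win_a = retained[["window_id", "chrom", "start", "end"]]
    win_b = retained[["window_id", "target_chrom", "target_start", "target_end"]] \
        .rename(columns={"target_chrom": "chrom", "target_start": "start",
                         "target_end": "end"})

    cds_a = read_gff_features(SIM_DIR / "genes_a.gff3", "CDS")
    covtab = build_covariate_table(
        win_a, cds=cds_a, repeats=read_bed(SIM_DIR / "repeats_a.bed"),
        genes_ds=pd.read_csv(SIM_DIR / "ds_a.tsv", sep="\t"),
        rec_by_window=read_tsv_covariate(SIM_DIR / "rec.tsv", ["window_id"], "rec_rate"),
        chrom_sizes=read_chrom_sizes(SIM_DIR / "ref.sizes"),
        gc_by_window=read_tsv_covariate(SIM_DIR / "gc_a.tsv", ["window_id"], "gc"),
        genes=read_gff_features(SIM_DIR / "genes_a.gff3", "gene"),
    )
    write_tsv(covtab, "results/covariates_a.tsv")

    pi_a = pd.read_csv("results/pi_a.tsv", sep="\t")
    pi_b = pd.read_csv("results/pi_b.tsv", sep="\t")
    merged = (
        pi_a[pi_a["qc_verdict"] == "kept"][["window_id", "pi_species"]]
        .rename(columns={"pi_species": "pi_a"})
        .merge(pi_b[pi_b["qc_verdict"] == "kept"][["window_id", "pi_species"]]
               .rename(columns={"pi_species": "pi_b"}), on="window_id")
        .merge(covtab, on="window_id"))

    corr = spearman(merged["pi_a"], merged["pi_b"])
    cds_b = read_gff_features(SIM_DIR / "genes_b.gff3", "CDS")
    masked = masked_species_pi("a", win_a, cds_a).merge(
        masked_species_pi("b", win_b, cds_b), on="window_id")
    corr_masked = spearman(masked["pi_a"], masked["pi_b"])
    print(f"cross-species Spearman rho = {corr.rho:.3f} (n={corr.n}, p={corr.p_value:.2g})")
    print(f"          with CDS masked = {corr_masked.rho:.3f}")

    t1 = chromosome_covariate_model(merged["pi_b"], merged["pi_a"], merged["chrom_length"])
    print(f"chromosome-length model: R2={t1.r2:.3f}, "
          f"t(other-species pi)={t1.t('pi_other'):.1f}, "
          f"t(chrom length)={t1.t('chrom_length'):.2f}")

    t2 = ols(merged["pi_a"], merged[PREDICTORS])
    print(f"five-predictor OLS: R2={t2.r2:.3f}, F({t2.df_model},{t2.df_resid})={t2.f_stat:.1f}")
    for p in PREDICTORS:
        print(f"  {p:15s} t={t2.t(p):+.2f} p={t2.p(p):.2g}")

    pc = pcr(merged["pi_a"], merged[PREDICTORS])
    print("PCR per-PC share of diversity variance:",
          np.array2string(pc.response_r2, precision=4))
    print(f"  sum = {pc.total_r2:.4f} (equals OLS R2)")

    deciles = {}
    for strat, col in (("cds", "cds_density"), ("gc", "gc")):
        for which in ("highest", "lowest"):
            fit = decile_stratified_regression(merged["pi_a"], merged["rec_log10"],
                                               merged[col], which,
                                               tiebreak=merged["window_id"])
            deciles[f"{strat}_{which}"] = {"slope": fit.coef("rec"),
                                           "t": fit.t("rec"), "p": fit.p("rec"),
                                           "r2": fit.r2, "n": fit.n}
            print(f"decile {strat}/{which:7s}: slope={fit.coef('rec'):+.2e} "
                  f"t={fit.t('rec'):+.2f} n={fit.n}")

    out = {
        "spearman": {"rho": corr.rho, "n": corr.n, "p": corr.p_value},
        "spearman_cds_masked": {"rho": corr_masked.rho, "n": corr_masked.n},
        "chromosome_length_model": {"r2": t1.r2, "t_chrom_length": t1.t("chrom_length")},
        "five_predictor_ols": {"r2": t2.r2, "f": t2.f_stat,
                               "t_values": {p: t2.t(p) for p in PREDICTORS}},
        "pcr": {"per_pc_r2": pc.response_r2.tolist(),
                "association_sign": pc.association_sign.tolist(),
                "loadings": pc.loadings.round(4).to_dict()},
        "decile_regressions": deciles,
    }
    Path("results/regressions.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
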