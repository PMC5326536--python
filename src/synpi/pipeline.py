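"""End-to-end orchestration: synteny -> diversity (± CDS mask) -> shared
polymorphism -> covariates -> correlation/regression/PCR.

Stages communicate through TSV files in the run directory so each stage is
independently inspectable and re-runnable; ``summary.json`` collects the
headline numbers and ``manifest.yaml`` the thresholds, inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import covariates as cov
from . import diversity as dv
from . import intervals as iv
from . import regress as rg
from . import shared_poly as sp
from .io import (load_population_sites, read_bed, read_chain_file, read_chrom_sizes,
                 read_gff_features, read_tsv_covariate, write_tsv)
from .synteny import ChainIndex, build_window_map, tile_windows

PREDICTORS = ["rec_log10", "cds_sqrt", "gc", "ds_sqrt", "repeat_density"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one run; defaults are the analysis defaults."""

    chains: str = ""
    ref_sizes: str = ""
    vcfs_a: list[str] = field(default_factory=list)
    vcfs_b: list[str] = field(default_factory=list)
    accessible_a: list[str] = field(default_factory=list)
    accessible_b: list[str] = field(default_factory=list)
    gff_a: str = ""
    gff_b: str = ""
    repeats_a: str = ""
    gc_a: str = ""
    gc_b: str = ""
    ds_a: str = ""
    rec: str = ""
    out_dir: str = "pipeline_out"
    window_size: int = 200_000
    min_remap: float = 0.80
    min_len: int = 180_000
    max_len: int = 220_000
    min_dp: int = 4
    min_sites: int = 10_000
    decile_fraction: float = 0.10
    outlier_k: float = 10.0
    drop_outliers: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_sim_dir(cls, sim_dir, out_dir) -> "PipelineConfig":
        """Point a config at the file layout of ``simulate_genome``."""
        d = Path(sim_dir)
        pops = sorted(p.name.split(".")[1] for p in d.glob("a.*.vcf"))
        return cls(
            chains=str(d / "a2b.chain"), ref_sizes=str(d / "ref.sizes"),
            vcfs_a=[str(d / f"a.{p}.vcf") for p in pops],
            vcfs_b=[str(d / f"b.{p}.vcf") for p in pops],
            accessible_a=[str(d / f"accessible_a.{p}.tsv") for p in pops],
            accessible_b=[str(d / f"accessible_b.{p}.tsv") for p in pops],
            gff_a=str(d / "genes_a.gff3"), gff_b=str(d / "genes_b.gff3"),
            repeats_a=str(d / "repeats_a.bed"),
            gc_a=str(d / "gc_a.tsv"), gc_b=str(d / "gc_b.tsv"),
            ds_a=str(d / "ds_a.tsv"), rec=str(d / "rec.tsv"),
            out_dir=str(out_dir),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage '{stage}' failed: {detail}")
        self.stage = stage


def _require(stage: str, *paths):
    for p in paths:
        if not p or not Path(p).exists():
            raise StageError(stage, f"missing input file: {p!r}")


def _species_diversity(cfg, vcfs, accessibles, windows, mask, stage, site_cache):
    _require(stage, *vcfs, *accessibles)
    tables = []
    for i, (vcf, acc_path) in enumerate(zip(vcfs, accessibles)):
        acc = read_tsv_covariate(acc_path, ["window_id"], "n_sites")
        if vcf not in site_cache:
            site_cache[vcf] = load_population_sites(vcf)
        tables.append(dv.compute_windowed_pi(
            vcf, windows, population=f"pop{i + 1}", min_dp=cfg.min_dp,
            accessible=acc, mask=mask, sites=site_cache[vcf]))
    return tables, dv.apply_window_qc(tables, min_sites=cfg.min_sites,
                                      outlier_k=cfg.outlier_k,
                                      drop_outliers=cfg.drop_outliers)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- synteny ----------------------------------------------------------
    _require("synteny", cfg.chains, cfg.ref_sizes)
    chrom_sizes = read_chrom_sizes(cfg.ref_sizes)
    windows = tile_windows(chrom_sizes, cfg.window_size)
    try:
        index = ChainIndex(read_chain_file(cfg.chains))
    except ValueError as exc:
        raise StageError("synteny", str(exc))
    wmap = build_window_map(windows, index, cfg.min_remap, cfg.min_len, cfg.max_len)
    write_tsv(wmap, out / "window_map.tsv")
    retained = wmap[wmap["verdict"] == "retained"].reset_index(drop=True)
    if len(retained) == 0:
        raise StageError("synteny", "no window passed the retention filters")
    win_a = retained[["window_id", "chrom", "start", "end"]]
    win_b = retained[["window_id", "target_chrom", "target_start", "target_end"]].rename(
        columns={"target_chrom": "chrom", "target_start": "start", "target_end": "end"})

    # --- diversity --------------------------------------------------------
    site_cache: dict = {}
    tabs_a, species_a = _species_diversity(cfg, cfg.vcfs_a, cfg.accessible_a,
                                           win_a, None, "diversity", site_cache)
    tabs_b, species_b = _species_diversity(cfg, cfg.vcfs_b, cfg.accessible_b,
                                           win_b, None, "diversity", site_cache)
    write_tsv(species_a, out / "pi_a.tsv")
    write_tsv(species_b, out / "pi_b.tsv")

    # --- diversity with coding sequence masked ----------------------------
    _require("cds_mask", cfg.gff_a, cfg.gff_b)
    cds_a = read_gff_features(cfg.gff_a, "CDS")
    cds_b = read_gff_features(cfg.gff_b, "CDS")
    mask_a, mask_b = iv.track_from_frame(cds_a), iv.track_from_frame(cds_b)
    _, species_a_m = _species_diversity(cfg, cfg.vcfs_a, cfg.accessible_a,
                                        win_a, mask_a, "cds_mask", site_cache)
    _, species_b_m = _species_diversity(cfg, cfg.vcfs_b, cfg.accessible_b,
                                        win_b, mask_b, "cds_mask", site_cache)

    # --- shared polymorphism audit ----------------------------------------
    report = sp.audit_shared_polymorphism(
        cfg.vcfs_a, cfg.vcfs_b, index, min_dp=cfg.min_dp,
        sites_a=[site_cache[v] for v in cfg.vcfs_a],
        sites_b=[site_cache[v] for v in cfg.vcfs_b])

    # --- covariates (species a frame) --------------------------------------
    _require("covariates", cfg.repeats_a, cfg.ds_a, cfg.rec, cfg.gc_a)
    genes_a = read_gff_features(cfg.gff_a, "gene")
    genes_ds = pd.read_csv(cfg.ds_a, sep="\t")
    covtab = cov.build_covariate_table(
        win_a, cds=cds_a, repeats=read_bed(cfg.repeats_a), genes_ds=genes_ds,
        rec_by_window=read_tsv_covariate(cfg.rec, ["window_id"], "rec_rate"),
        chrom_sizes=chrom_sizes,
        gc_by_window=read_tsv_covariate(cfg.gc_a, ["window_id"], "gc"),
        genes=genes_a,
    )
    write_tsv(covtab, out / "covariates_a.tsv")

    # --- merge + statistics -------------------------------------------------
    kept_a = species_a[species_a["qc_verdict"] == "kept"]
    kept_b = species_b[species_b["qc_verdict"] == "kept"]
    merged = kept_a[["window_id", "pi_species"]].rename(columns={"pi_species": "pi_a"}) \
        .merge(kept_b[["window_id", "pi_species"]].rename(columns={"pi_species": "pi_b"}),
               on="window_id").merge(covtab, on="window_id")
    write_tsv(merged, out / "windows_merged.tsv")
    if len(merged) < 10:
        raise StageError("regress", f"only {len(merged)} analysable windows")

    corr = rg.spearman(merged["pi_a"], merged["pi_b"])
    merged_m = species_a_m[species_a_m["qc_verdict"] == "kept"][
        ["window_id", "pi_species"]].rename(columns={"pi_species": "pi_a"}).merge(
        species_b_m[species_b_m["qc_verdict"] == "kept"][
            ["window_id", "pi_species"]].rename(columns={"pi_species": "pi_b"}),
        on="window_id")
    corr_masked = rg.spearman(merged_m["pi_a"], merged_m["pi_b"])

    table1 = rg.chromosome_covariate_model(merged["pi_b"], merged["pi_a"],
                                           merged["chrom_length"])
    X = merged[PREDICTORS]
    table2 = rg.ols(merged["pi_a"], X)
    pcr_res = rg.pcr(merged["pi_a"], X)
    deciles = {}
    for strat, col in (("cds", "cds_density"), ("gc", "gc")):
        for which in ("highest", "lowest"):
            fit = rg.decile_stratified_regression(
                merged["pi_a"], merged["rec_log10"], merged[col], which,
                fraction=cfg.decile_fraction,
                tiebreak=merged["window_id"])
            deciles[f"{strat}_{which}"] = {
                "slope": fit.coef("rec"), "t": fit.t("rec"), "p": fit.p("rec"),
                "r2": fit.r2, "n": fit.n, "df_resid": fit.df_resid,
            }

    summary = {
        "n_windows_tiled": int(windows["full"].sum()),
        "n_windows_retained": int(len(retained)),
        "retained_fraction": float(len(retained) / windows["full"].sum()),
        "n_windows_analysed": int(len(merged)),
        "pi_mean_a": float(merged["pi_a"].mean()),
        "pi_mean_b": float(merged["pi_b"].mean()),
        "spearman_rho": corr.rho, "spearman_p": corr.p_value, "spearman_n": corr.n,
        "spearman_rho_cds_masked": corr_masked.rho,
        "shared_polymorphism": {
            "n_variable_a": report.n_variable_A,
            "n_alignable_variable_a": report.n_alignable_variable_A,
            "n_also_variable_b": report.n_also_variable_B,
            "fraction": report.fraction,
        },
        "table1": {
            "r2": table1.r2, "f": table1.f_stat,
            "t_pi_other": table1.t("pi_other"),
            "t_chrom_length": table1.t("chrom_length"),
            "p_chrom_length": table1.p("chrom_length"),
        },
        "table2": {
            "r2": table2.r2, "f": table2.f_stat, "n": table2.n,
            "t_values": {p: table2.t(p) for p in PREDICTORS},
        },
        "pcr": {
            "per_pc_r2": [float(x) for x in pcr_res.response_r2],
            "total_r2": pcr_res.total_r2,
            "association_sign": [int(x) for x in pcr_res.association_sign],
        },
        "decile_regressions": deciles,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        "synpi_version": __version__,
        "config": asdict(cfg),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return summary


def load_summary(run_dir) -> dict:
    with open(Path(run_dir) / "summary.json") as fh:
        return json.load(fh)
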