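# synpi — diversity covariation across conserved synteny

`synpi` asks whether two long-diverged genomes still show correlated levels of
nucleotide diversity (π) in homologous regions — the signature expected when a
conserved recombination landscape and a conserved distribution of selection
targets make linked selection act in parallel, long after lineage sorting has
removed all shared ancestral polymorphism. It is aimed at population
genomicists who have, for a pair of species: a pairwise-alignment chain file,
per-population variant calls, and window-level genomic covariates.

The pipeline:

1. **Synteny mapping** — tile one genome into non-overlapping 200 kb windows
   and lift each through UCSC chains; keep a window only if >80% of its bases
   map into one contiguous target run of 180–220 kb.
2. **Windowed diversity** — per population, π per window is

   π̂ = Σ_variable sites [ 2 p̂(1−p̂) · n/(n−1) ] / (accessible sites),

   where p̂ is the alternate-allele frequency among the n called allele copies
   and a site is accessible when every individual has depth ≥ 4; windows with
   <10 000 accessible sites in any population are dropped, species values are
   the mean of the two populations. The estimator equals the mean pairwise
   difference per site between sampled haplotypes and is phase-free.
3. **Trans-species polymorphism audit** — count sites variable in ≥1
   population of species A that lift to species B and are variable there too.
4. **Covariates** — per window: recombination rate (log10(x+1)), CDS density
   (√), gene-length-weighted dS (√, after excluding dS=0 and dS>2 genes and
   windows averaging >0.3), intergenic GC, repeat density, chromosome length.
5. **Statistics** — cross-species Spearman ρ (with and without CDS masked),
   OLS of one species' π on the other's plus chromosome length, the
   five-predictor OLS, principal component regression (per-PC shares of π
   variance sum exactly to the OLS R²), and diversity~recombination fits in
   the top/bottom coding-density (or GC) deciles.

Because real two-species resequencing data are not desk-scale, the package
ships a synthetic generator (`synpi.simulate`) producing chains, VCFs, GFF3/
BED annotations and covariate TSVs for two species whose expected window
diversity follows a background-selection law
E[π] = 4·N_e·μ·m_w·exp(−k·d_w/(r_w+ε)) over a landscape shared between
species with a tunable coefficient `s`, with the ground truth recorded for
every window.

## Worked example

The numbered scripts under `analysis/` run the whole study on a small
synthetic genome (2 chromosomes, 80 windows, 15 diploids per population):

```bash
python analysis/01_simulate_genomes.py
python analysis/02_map_synteny.py
python analysis/03_window_diversity.py
python analysis/04_shared_polymorphism.py
python analysis/05_covariates_and_regressions.py
python analysis/06_simulation_experiments.py
```

Step 02 prints the retention bookkeeping,

```
retained         77
unmapped          2
rejected_size     1
retained 77/80 full windows (96.2%) -> results/window_map.tsv
agreement with generator truth: 100.0%
```

step 03 the species diversity levels (the two species are simulated at
roughly 4:1 diversity, mirroring typical passerine contrasts),

```
species a: 76/77 windows kept, mean pi = 0.00429 (range 0.00126-0.01068)
species b: 76/77 windows kept, mean pi = 0.00129 (range 0.00053-0.00266)
```

and step 05 the cross-species correlation, which survives masking all coding
sequence — the covariation is not driven by the genes themselves:

```
cross-species Spearman rho = 0.336 (n=76, p=0.003)
          with CDS masked = 0.341
```

At this toy scale the per-predictor t-values are noisy; step 06 repeats the
regressions at the 3000-window scale, where the linked-selection signature is
recovered essentially always:

```
correlation recovery (10 genomes): max |rho_hat - rho_designed| = 0.0052
effect signs over 25 genomes: rec>0 in 25, cds<0 in 25, high-CDS decile slope steeper in 24
null control (k=0, s=0): rho = -0.0037
```

The same machinery is scriptable: `synpi simulate`, `synpi liftmap`,
`synpi run --config run.yaml` (full pipeline from a YAML config) and
`synpi summary --dir out/`.

## Layout

```
src/synpi/        io, intervals, synteny, diversity, shared_poly,
                  covariates, regress, simulate, pipeline, cli
analysis/         numbered drivers reproducing the study on synthetic data
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   model, estimators, generator and design notes
```
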