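"""Trans-species polymorphism audit.

After complete lineage sorting two species should share essentially no
segregating variants; residual overlap reflects coincident recurrent
mutation. The audit counts sites variable in at least one population of
species A that can be lifted to species B coordinates, and asks how many of
those coincide with sites variable in at least one population of B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import PopulationSites, load_population_sites
from .synteny import ChainIndex


@dataclass
class SharedPolymorphismReport:
    n_variable_A: int            # passing variable sites in species A (any pop)
    n_alignable_variable_A: int  # of those, liftable to species B (denominator)
    n_also_variable_B: int       # coinciding with a variable site in species B
    fraction: float              # numerator / denominator (NaN when denominator 0)
    n_variable_A_unfiltered: int  # before the coverage filter, for reference


def _variable_sets(pops: Sequence[PopulationSites], min_dp: int):
    """Per-chrom sorted unique variable positions; filtered and unfiltered."""
    filt: dict[str, list[np.ndarray]] = {}
    unfilt: dict[str, list[np.ndarray]] = {}
    alleles: dict[tuple[str, int], str] = {}
    for pop in pops:
        for chrom in pop.chroms:
            alt, called = pop.alt_count[chrom], pop.called_count[chrom]
            variable = (alt > 0) & (alt < called)
            passing = variable & (pop.min_depth[chrom] >= min_dp)
            unfilt.setdefault(chrom, []).append(pop.pos0[chrom][variable])
            filt.setdefault(chrom, []).append(pop.pos0[chrom][passing])
            for p, a in zip(pop.pos0[chrom][passing], pop.alt[chrom][passing]):
                alleles[(chrom, int(p))] = str(a)
    out_f = {c: np.unique(np.concatenate(v)) for c, v in filt.items()}
    out_u = {c: np.unique(np.concatenate(v)) for c, v in unfilt.items()}
    return out_f, out_u, alleles


def audit_shared_polymorphism(
    vcfs_a: Sequence,
    vcfs_b: Sequence,
    chains,
    min_dp: int = 4,
    allele_aware: bool = False,
    sites_a: Optional[Sequence[PopulationSites]] = None,
    sites_b: Optional[Sequence[PopulationSites]] = None,
) -> SharedPolymorphismReport:
    """Count species-A variable sites that lift to B and are variable there too.

    A site is "variable in a species" when it is a coverage-passing
    bi-allelic SNP in at least one of that species' populations. Matching is
    by lifted coordinate; ``allele_aware`` additionally requires the same
    alternate base. Sites failing coverage in every population count as
    non-variable. A-sites that fall in chain gaps never enter the
    denominator.
    """
    if chains is None:
        raise ValueError("a chain set mapping species A to species B is required")
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    pops_a = list(sites_a) if sites_a is not None else [load_population_sites(v) for v in vcfs_a]
    pops_b = list(sites_b) if sites_b is not None else [load_population_sites(v) for v in vcfs_b]
    var_a, var_a_unf, alleles_a = _variable_sets(pops_a, min_dp)
    var_b, _, alleles_b = _variable_sets(pops_b, min_dp)

    n_var_a = sum(len(v) for v in var_a.values())
    n_var_a_unf = sum(len(v) for v in var_a_unf.values())
    n_align = 0
    n_shared = 0
    b_sets = {c: v for c, v in var_b.items()}
    for chrom, pos in var_a.items():
        ok, tchrom, tpos = index.lift_positions(chrom, pos)
        n_align += int(ok.sum())
        for i in np.nonzero(ok)[0]:
            bset = b_sets.get(tchrom[i])
            if bset is None:
                continue
            j = np.searchsorted(bset, tpos[i])
            hit = j < len(bset) and bset[j] == tpos[i]
            if hit and allele_aware:
                hit = alleles_a.get((chrom, int(pos[i]))) == alleles_b.get(
                    (str(tchrom[i]), int(tpos[i])))
            if hit:
                n_shared += 1
    frac = n_shared / n_align if n_align > 0 else float("nan")
    return SharedPolymorphismReport(n_var_a, n_align, n_shared, frac, n_var_a_unf)
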