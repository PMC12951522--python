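"""Differential fixation: per-species fixed differences and morphotype set algebra.

A site is differentially fixed for species s when s is fixed for one allele
and every other panel species is fixed for the other allele. At gene level,
candidate sets for each morphotype intersect the within-morph species' gene
sets and subtract the union of the opposite morph's (two-species mode)

    fixed_slender = (fixed_sA ∩ fixed_sB) \\ (fixed_tA ∪ fixed_tB)
    fixed_stout   = (fixed_tA ∩ fixed_tB) \\ (fixed_sA ∪ fixed_sB)

or, in all-species mode, include the extra stout species in both the stout
intersection and the slender subtraction. Significance of within-morphotype
gene sharing comes from enumerating morphotype-label reassignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .frequencies import AlleleFrequencyTable
from .panel import Pairing
from .variants import VariantTable


@dataclass
class FixedSiteSets:
    """Per-species sets of differentially fixed site indices (pairwise disjoint)."""

    sets: dict[str, set[int]]

    def __post_init__(self) -> None:
        species = list(self.sets)
        for a, b in combinations(species, 2):
            if self.sets[a] & self.sets[b]:
                raise ValueError(
                    f"fixed-site sets of {a!r} and {b!r} overlap — a site can "
                    "be differentially fixed for at most one species"
                )


def species_fixed_sites(
    af: AlleleFrequencyTable,
    species_list: list[str] | None = None,
    min_copies: int = 8,
) -> FixedSiteSets:
    """Sites where one species is fixed for one allele and all others for the other.

    Fixation uses exact frequency bounds (0 or 1) on called copies; species
    with fewer than ``min_copies`` called copies at a site make the site
    ineligible, guarding against spurious fixation from missingness. Sites
    with any undefined species frequency are skipped.
    """
    species_list = species_list or af.species
    if len(species_list) < 2:
        raise ValueError("at least two species required")
    cols = [af.species.index(s) for s in species_list]
    sub = af.af[:, cols]
    ncall = af.n_called[:, cols]
    ok = np.isfinite(sub).all(axis=1) & (ncall >= min_copies).all(axis=1)
    at_zero = sub == 0.0
    at_one = sub == 1.0
    all_fixed = (at_zero | at_one).all(axis=1)
    n_one = at_one.sum(axis=1)
    sets: dict[str, set[int]] = {s: set() for s in species_list}
    # The focal species carries the minority allele: exactly one species at 1
    # (others at 0) or exactly one at 0 (others at 1).
    cand = np.flatnonzero(ok & all_fixed & ((n_one == 1) | (n_one == len(cols) - 1)))
    for i in cand:
        if n_one[i] == 1:
            j = int(np.flatnonzero(at_one[i])[0])
        else:
            j = int(np.flatnonzero(at_zero[i])[0])
        sets[species_list[j]].add(int(i))
    return FixedSiteSets(sets)


def sites_to_genes(sites: set[int], vt: VariantTable) -> set[str]:
    """Deduplicated gene IDs annotated to a set of site indices."""
    genes = vt.df["gene"]
    return {genes.iloc[i] for i in sites if isinstance(genes.iloc[i], str)}


@dataclass
class MorphCandidateGenes:
    fixed_slender: set[str]
    fixed_stout: set[str]
    fixed_union: set[str]
    mode: str  # "two_species" | "all_species"
    overlap: set[str]  # genes landing in both morph sets (distinct sites)


def morph_candidate_genes(
    fixed: FixedSiteSets,
    vt: VariantTable,
    pairing: Pairing,
    mode: str = "two_species",
    extra_stout: str | None = None,
) -> MorphCandidateGenes:
    """Morphotype candidate-gene set algebra at gene level.

    ``two_species`` uses only the four pairing species; ``all_species`` adds
    ``extra_stout`` (the fifth species, stout morphotype) to the stout
    intersection and the slender subtraction. Genes reached by distinct sites
    in both morph sets are recorded in ``overlap``, not silently merged.
    """
    for sp in pairing.species():
        if sp not in fixed.sets:
            raise ValueError(f"pairing species {sp!r} absent from fixed sets")
    g = {sp: sites_to_genes(fixed.sets[sp], vt) for sp in fixed.sets}
    sa, ta = pairing.slender_a, pairing.stout_a
    sb, tb = pairing.slender_b, pairing.stout_b
    if mode == "two_species":
        slender = (g[sa] & g[sb]) - (g[ta] | g[tb])
        stout = (g[ta] & g[tb]) - (g[sa] | g[sb])
    elif mode == "all_species":
        if extra_stout is None or extra_stout not in g:
            raise ValueError("all_species mode needs extra_stout present in sets")
        slender = (g[sa] & g[sb]) - (g[extra_stout] | g[ta] | g[tb])
        stout = (g[ta] & g[tb] & g[extra_stout]) - (g[sa] | g[sb])
    else:
        raise ValueError("mode must be 'two_species' or 'all_species'")
    return MorphCandidateGenes(
        slender, stout, slender | stout, mode, overlap=slender & stout
    )


def morph_overlap_permutation(
    gene_sets: dict[str, set[str]], pairing: Pairing
) -> tuple[int, float, list[int]]:
    """Exact permutation test of within-morphotype gene sharing.

    The statistic is the number of genes shared within morphotypes after
    subtracting the opposite morph (|fixed_slender| + |fixed_stout| under the
    set algebra above). The null enumerates all 3 balanced 2+2 partitions of
    the four pairing species into pseudo-morphotypes; p is the fraction of
    partitions whose statistic is at least the observed one (the true
    partition included, so the floor is 1/3).

    Returns (observed, p, all partition statistics).
    """
    four = list(pairing.species())
    for sp in four:
        if sp not in gene_sets:
            raise ValueError(f"species {sp!r} missing from gene sets")

    def statistic(group1: tuple[str, str], group2: tuple[str, str]) -> int:
        a = (gene_sets[group1[0]] & gene_sets[group1[1]]) - (
            gene_sets[group2[0]] | gene_sets[group2[1]]
        )
        b = (gene_sets[group2[0]] & gene_sets[group2[1]]) - (
            gene_sets[group1[0]] | gene_sets[group1[1]]
        )
        return len(a) + len(b)

    partitions = []
    rest = four[1:]
    for partner in rest:
        g1 = (four[0], partner)
        g2 = tuple(s for s in rest if s != partner)
        partitions.append((g1, g2))
    true_g1 = (pairing.slender_a, pairing.slender_b)
    stats_all = [statistic(g1, g2) for g1, g2 in partitions]
    observed = statistic(true_g1, (pairing.stout_a, pairing.stout_b))
    p = sum(s >= observed for s in stats_all) / len(partitions)
    return observed, p, stats_all
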