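"""Shared fixtures: small panels, hand-built frequency tables, a reference
simulation, and brute-force oracle helpers used across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from convergescan import (AlleleFrequencyTable, Pairing, SpeciesPanel,
                          VariantTable)

SPECIES5 = ["slenderA", "stoutA", "slenderB", "stoutB", "stoutC"]
MORPHS5 = {
    "slenderA": "slender", "stoutA": "stout", "slenderB": "slender",
    "stoutB": "stout", "stoutC": "stout",
}

#: star-shaped species tree (independent drift, no shared internal branches)
STAR_TREE = "(slenderA:{f},stoutA:{f},slenderB:{f},stoutB:{f},stoutC:{f});"


def make_panel(n_per_species: int = 2, species=None, morphs=None) -> SpeciesPanel:
    species = species or SPECIES5
    morphs = morphs or MORPHS5
    samples, species_of = [], {}
    for sp in species:
        for i in range(n_per_species):
            s = f"{sp}_{i}"
            samples.append(s)
            species_of[s] = sp
    slender = [sp for sp in species if morphs[sp] == "slender"]
    stout = [sp for sp in species if morphs[sp] == "stout"]
    pairing = Pairing(slender[0], stout[0], slender[1], stout[1])
    return SpeciesPanel(samples, species_of, dict(morphs), pairing)


def make_af(freqs, species=None, copies: int = 20) -> AlleleFrequencyTable:
    """Frequency table from an (n_sites, n_species) array of frequencies."""
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    species = species or SPECIES5[: freqs.shape[1]]
    n_called = np.where(np.isfinite(freqs), copies, 0)
    return AlleleFrequencyTable(freqs, n_called, list(species))


def make_variant_table(n: int, chrom: str = "chr1", spacing: int = 100,
                       genes=None, effects=None) -> VariantTable:
    df = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.arange(1, n + 1) * spacing,
            "ref": ["A"] * n,
            "alt": ["T"] * n,
        }
    )
    if genes is not None:
        df["gene"] = genes
    if effects is not None:
        df["effect"] = effects
    return VariantTable(df)


@pytest.fixture()
def pairing() -> Pairing:
    return Pairing("slenderA", "stoutA", "slenderB", "stoutB")


# ---------------------------------------------------------------- oracles

def pi_site_oracle(dosages: np.ndarray) -> float:
    """Fraction of differing unordered allele-copy pairs at one site."""
    alleles = []
    for g in dosages:
        if g < 0:
            continue
        alleles += [1] * int(g) + [0] * (2 - int(g))
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = sum(
        alleles[i] != alleles[j] for i in range(n) for j in range(i + 1, n)
    )
    return diff / (n * (n - 1) / 2)


def dxy_site_oracle(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Mean difference over all between-species allele-copy pairs."""
    def copies(dosages):
        out = []
        for g in dosages:
            if g >= 0:
                out += [1] * int(g) + [0] * (2 - int(g))
        return out

    ca, cb = copies(dos_a), copies(dos_b)
    if not ca or not cb:
        return 0.0
    return float(np.mean([[a != b for b in cb] for a in ca]))


def hypergeom_tail_oracle(k: int, big_n: int, big_k: int, n: int) -> float:
    """Upper-tail P[X >= k] by explicit summation of the pmf."""
    from math import comb

    total = comb(big_n, n)
    return sum(
        comb(big_k, x) * comb(big_n - big_k, n - x)
        for x in range(k, min(big_k, n) + 1)
    ) / total


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs + 1e-12)
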