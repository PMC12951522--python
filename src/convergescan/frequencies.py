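"""Per-species alternative-allele frequencies from diploid dosages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import SpeciesPanel
from .variants import MISSING, GenotypeMatrix, VariantTable


@dataclass
class AlleleFrequencyTable:
    """Alt-allele frequency per variant x species.

    af       : (n_variants, n_species) float; NaN where no copies were called
    n_called : (n_variants, n_species) int, called allele copies (2 per
               non-missing diploid genotype)
    species  : column order
    """

    af: np.ndarray
    n_called: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.af = np.asarray(self.af, dtype=float)
        self.n_called = np.asarray(self.n_called, dtype=np.int64)
        if self.af.shape != self.n_called.shape:
            raise ValueError("af and n_called shapes differ")
        if self.af.shape[1] != len(self.species):
            raise ValueError("species list does not match af columns")
        finite = np.isfinite(self.af)
        if finite.any() and ((self.af[finite] < 0) | (self.af[finite] > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_variants(self) -> int:
        return self.af.shape[0]

    def col(self, species: str) -> np.ndarray:
        return self.af[:, self.species.index(species)]

    def defined(self, species_subset: list[str] | None = None) -> np.ndarray:
        """Sites where every (listed) species has at least one called copy."""
        cols = (
            slice(None)
            if species_subset is None
            else [self.species.index(s) for s in species_subset]
        )
        return np.isfinite(self.af[:, cols]).all(axis=1)

    def to_dataframe(self, vt: VariantTable) -> pd.DataFrame:
        out = vt.df[["chrom", "pos"]].copy()
        for j, sp in enumerate(self.species):
            out[f"af_{sp}"] = self.af[:, j]
        return out


def allele_frequencies(gt: GenotypeMatrix, panel: SpeciesPanel) -> AlleleFrequencyTable:
    """Per-species alt-allele frequency: alt copies / called copies.

    A species-site with no called genotypes gets af = NaN (flagged undefined,
    never zero-filled).
    """
    species = panel.species()
    n_var = gt.n_variants
    af = np.full((n_var, len(species)), np.nan)
    n_called = np.zeros((n_var, len(species)), dtype=np.int64)
    for j, sp in enumerate(species):
        idx = panel.sample_indices(sp)
        sub = gt.calls[:, idx]
        called = sub != MISSING
        copies = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        n_called[:, j] = copies
        with np.errstate(invalid="ignore", divide="ignore"):
            af[:, j] = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
    return AlleleFrequencyTable(af, n_called, species)
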