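"""Per-site convergence score and outlier machinery.

The convergence score at a biallelic site is the product of the slender–stout
allele-frequency differences in two independent species pairs,

    score = (AF_slenderA - AF_stoutA) * (AF_slenderB - AF_stoutB),

so a positive score means the same allele shifted in the same direction in
both pairs (convergence), a negative score an opposite-direction shift
(divergence), and +1 requires opposite fixation within both pairs. The score
is invariant to which allele is labelled reference: flipping af -> 1-af
negates both factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .frequencies import AlleleFrequencyTable
from .panel import Pairing
from .variants import VariantTable


@dataclass
class ScoreTrack:
    """Per-variant convergence score with a definedness flag.

    score   : (n_variants,) float in [-1, 1]; meaningful only where defined
    defined : False where any of the four pairing species has an undefined
              allele frequency (those sites are excluded from all downstream
              counts, never zero-filled)
    """

    score: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        ok = self.score[self.defined]
        if ok.size and (np.abs(ok) > 1 + 1e-12).any():
            raise ValueError("convergence scores must lie in [-1, 1]")


@dataclass
class OutlierSets:
    """Index sets of outlier sites at a symmetric score threshold."""

    positive: np.ndarray  # indices with score >= threshold (or > when strict)
    negative: np.ndarray  # indices with score <= -threshold
    fixed_convergent: np.ndarray  # indices with score == 1
    threshold: float = 0.25

    def __post_init__(self) -> None:
        if set(self.fixed_convergent) - set(self.positive):
            raise ValueError("fixed-convergent sites must be positive outliers")
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative outlier sets overlap")


def convergence_score(af: AlleleFrequencyTable, pairing: Pairing) -> ScoreTrack:
    """Score every site; sites with any undefined pairing frequency are flagged."""
    missing = [s for s in pairing.species() if s not in af.species]
    if missing:
        raise ValueError(f"pairing species missing from frequency table: {missing}")
    sa, ta = af.col(pairing.slender_a), af.col(pairing.stout_a)
    sb, tb = af.col(pairing.slender_b), af.col(pairing.stout_b)
    defined = (
        np.isfinite(sa) & np.isfinite(ta) & np.isfinite(sb) & np.isfinite(tb)
    )
    score = np.where(defined, (sa - ta) * (sb - tb), np.nan)
    return ScoreTrack(score, defined)


def classify_sites(
    track: ScoreTrack, threshold: float = 0.25, strict: bool = False
) -> OutlierSets:
    """Partition defined sites into positive/negative outliers at ±threshold.

    With ``strict`` the comparison is > / < rather than >= / <=; the
    convergently-fixed set (score exactly 1) is reported either way.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    s = track.score
    d = track.defined
    if strict:
        pos = np.flatnonzero(d & (s > threshold))
        neg = np.flatnonzero(d & (s < -threshold))
    else:
        pos = np.flatnonzero(d & (s >= threshold))
        neg = np.flatnonzero(d & (s <= -threshold))
    fixed = np.flatnonzero(d & (s == 1.0))
    return OutlierSets(pos, neg, fixed, threshold)


@dataclass
class ExcessTestResult:
    """Two-sided exact binomial test of convergent vs divergent site counts."""

    n_convergent: int
    n_divergent: int
    p_value: float


def excess_binomial_test(n_pos: int, n_neg: int) -> ExcessTestResult:
    """Exact two-sided binomial test at p = 0.5 on nonzero-score counts.

    Two-sidedness follows the minimum-likelihood convention (sum of the
    probabilities of all outcomes no more likely than the observed count),
    which is scipy's default.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    if n_pos + n_neg == 0:
        raise ValueError("at least one nonzero-score site is required")
    p = stats.binomtest(n_pos, n_pos + n_neg, 0.5, alternative="two-sided").pvalue
    return ExcessTestResult(n_pos, n_neg, float(p))


def partition_genes_by_sign(
    outliers: OutlierSets, vt: VariantTable
) -> tuple[set[str], set[str], set[str]]:
    """Split genes by the sign of their outlier variants.

    Returns (positive_only, negative_only, both). Outlier sites without a
    gene annotation are skipped.
    """
    genes = vt.df["gene"]
    pos_genes = {g for g in genes.iloc[outliers.positive] if isinstance(g, str)}
    neg_genes = {g for g in genes.iloc[outliers.negative] if isinstance(g, str)}
    both = pos_genes & neg_genes
    return pos_genes - both, neg_genes - both, both
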