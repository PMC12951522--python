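"""Genotype-level site filters for a multi-species variant call set.

Sites are dropped when they show excessive missingness, total depth outside
central percentiles of the genome-wide per-site depth distribution, or an
inbreeding coefficient indicating excess heterozygosity. Individual
heterozygous calls with significantly imbalanced ref/alt read depths (exact
binomial, PHRED-scaled) are set missing before the missingness filter is
applied, so a site is only lost when enough of its calls are unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .variants import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for site-level genotype filters.

    max_missing_frac : drop sites with more than this fraction of missing calls
    depth_low_pct / depth_high_pct : central-percentile band on per-site total
        depth, computed once on the pre-filter distribution
    het_balance_phred : heterozygous calls whose ref/alt depths fail a
        two-sided exact binomial test (p = 0.5) at PHRED = -10*log10(p) above
        this value are set missing
    inbreeding_coeff_min : drop sites with F = 1 - Het_obs/Het_exp below this
        (negative F = excess heterozygosity, the usual artefact signature of
        paralogous mapping)
    """

    max_missing_frac: float = 0.20
    depth_low_pct: float = 2.5
    depth_high_pct: float = 97.5
    het_balance_phred: float = 20.0
    inbreeding_coeff_min: float = -0.2
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0.0 <= self.depth_low_pct < self.depth_high_pct <= 100.0:
            raise ValueError("depth percentiles must satisfy 0 <= low < high <= 100")


@dataclass
class FilterReport:
    """Counts of sites removed (or calls masked) by each filter."""

    n_input: int = 0
    n_het_calls_masked: int = 0
    n_missingness: int = 0
    n_depth: int = 0
    n_inbreeding: int = 0
    n_kept: int = 0
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_het_calls_masked": self.n_het_calls_masked,
            "n_removed_missingness": self.n_missingness,
            "n_removed_depth": self.n_depth,
            "n_removed_inbreeding": self.n_inbreeding,
            "n_kept": self.n_kept,
        }


def _het_balance_phred(ad: np.ndarray) -> np.ndarray:
    """PHRED score of a two-sided exact binomial test on (ref, alt) depths.

    Vectorised over unique (k, n) pairs; p = 0.5 under balanced sampling of
    the two alleles in a true heterozygote.
    """
    ref = ad[..., 0].astype(np.int64)
    alt = ad[..., 1].astype(np.int64)
    n = ref + alt
    k = alt
    phred = np.zeros(n.shape, dtype=float)
    pairs = np.unique(np.stack([k[n > 0], n[n > 0]], axis=-1).reshape(-1, 2), axis=0)
    pcache = {
        (int(kk), int(nn)): stats.binomtest(int(kk), int(nn), 0.5).pvalue
        for kk, nn in pairs
    }
    it = np.nditer(n, flags=["multi_index"])
    for nn in it:
        if nn > 0:
            p = pcache[(int(k[it.multi_index]), int(nn))]
            phred[it.multi_index] = -10.0 * np.log10(max(p, 1e-300))
    return phred


def apply_site_filters(
    gt: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[np.ndarray, GenotypeMatrix, FilterReport]:
    """Apply site filters; returns (keep mask, masked genotypes, report).

    Depth-based filters are skipped with a warning when the matrix carries no
    depth evidence. The keep mask refers to the input variant order; the
    returned matrix has het-imbalanced calls set missing but is NOT subset —
    callers subset both table and matrix by the mask.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=gt.n_variants)
    calls = gt.calls.copy()

    # 1. Mask individually unreliable heterozygous calls.
    if gt.ad is not None:
        het = calls == 1
        if het.any():
            phred = np.zeros_like(calls, dtype=float)
            phred[het] = _het_balance_phred(gt.ad[het])
            bad = het & (phred > cfg.het_balance_phred)
            report.n_het_calls_masked = int(bad.sum())
            calls[bad] = MISSING
    else:
        log.warning("no AD field: het allele-balance filter skipped")

    keep = np.ones(gt.n_variants, dtype=bool)

    # 2. Missingness cap (after call masking).
    miss = (calls == MISSING).mean(axis=1)
    drop = miss > cfg.max_missing_frac
    report.n_missingness = int(drop.sum())
    keep &= ~drop

    # 3. Central band of per-site total depth, percentiles on the full input.
    if gt.depth is not None:
        site_depth = gt.depth.sum(axis=1)
        lo, hi = np.percentile(site_depth, [cfg.depth_low_pct, cfg.depth_high_pct])
        drop = (site_depth < lo) | (site_depth > hi)
        report.n_depth = int((drop & keep).sum())
        keep &= ~drop
    else:
        log.warning("no DP field: depth percentile filter skipped")

    # 4. Inbreeding coefficient F = 1 - Het_obs/Het_exp across all samples.
    called = calls != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_copies = np.where(called, calls, 0).sum(axis=1)
        p = alt_copies / (2.0 * n_called)
        het_exp = 2.0 * p * (1.0 - p)
        het_obs = (calls == 1).sum(axis=1) / np.maximum(n_called, 1)
        f = np.where(het_exp > 0, 1.0 - het_obs / np.where(het_exp > 0, het_exp, 1.0), 0.0)
    drop = f < cfg.inbreeding_coeff_min
    report.n_inbreeding = int((drop & keep).sum())
    keep &= ~drop

    report.n_kept = int(keep.sum())
    masked = GenotypeMatrix(calls, gt.depth, gt.ad)
    return keep, masked, report
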