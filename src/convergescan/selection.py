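"""McDonald–Kreitman machinery: per-gene counts, NI, pooled NI_TG, DoS, Fisher.

For a species pair, a coding site is a divergence when the two species are
fixed for opposite alleles, and a polymorphism when it segregates in either
species without being a fixed difference. Counts split by effect class
(nonsynonymous vs synonymous) give the 2x2 MK table per gene. The neutrality
index NI = (Pn/Ps)/(Dn/Ds) is < 1 under an excess of fixed amino-acid
changes (positive selection); the Tarone–Greenland pooled estimator

    NI_TG = sum_i Ds_i Pn_i/(Ps_i+Ds_i) / sum_i Dn_i Ps_i/(Ps_i+Ds_i)

resists the small-count bias of averaging per-gene NI. DoS =
Dn/(Dn+Ds) - Pn/(Pn+Ps) is positive under adaptive divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .frequencies import AlleleFrequencyTable
from .variants import VariantTable


@dataclass(frozen=True)
class MKCounts:
    gene: str
    dn: int
    ds: int
    pn: int
    ps: int

    def __post_init__(self) -> None:
        if min(self.dn, self.ds, self.pn, self.ps) < 0:
            raise ValueError("MK counts must be nonnegative")


def mk_counts(
    vt: VariantTable, af: AlleleFrequencyTable, species_a: str, species_b: str
) -> list[MKCounts]:
    """Per-gene MK contingency counts for one species pair.

    Only annotated coding variants (synonymous / nonsynonymous effect) enter;
    a site segregating in both species is counted once as a polymorphism.
    Genes with no coding variants are absent from the result.
    """
    if species_a == species_b:
        raise ValueError("species pair must be two distinct species")
    pa, pb = af.col(species_a), af.col(species_b)
    genes = vt.df["gene"].to_numpy()
    effects = vt.df["effect"].to_numpy()
    ok = np.isfinite(pa) & np.isfinite(pb)
    coding = np.isin(effects, ("synonymous", "nonsynonymous"))
    has_gene = np.array([isinstance(g, str) for g in genes])
    fixed_diff = ((pa == 0.0) & (pb == 1.0)) | ((pa == 1.0) & (pb == 0.0))
    seg = ((pa > 0) & (pa < 1)) | ((pb > 0) & (pb < 1))
    poly = seg & ~fixed_diff
    use = ok & coding & has_gene & (fixed_diff | poly)

    tally: dict[str, list[int]] = {}
    for i in np.flatnonzero(use):
        row = tally.setdefault(genes[i], [0, 0, 0, 0])
        nonsyn = effects[i] == "nonsynonymous"
        if fixed_diff[i]:
            row[0 if nonsyn else 1] += 1
        else:
            row[2 if nonsyn else 3] += 1
    return [MKCounts(g, *c) for g, c in sorted(tally.items())]


def neutrality_index(c: MKCounts) -> float:
    """NI = (Pn/Ps)/(Dn/Ds); NaN when any required margin is zero."""
    if c.ps == 0 or c.dn == 0 or c.ds == 0:
        return np.nan
    return (c.pn / c.ps) / (c.dn / c.ds)


def ni_tg_point(genes: list[MKCounts]) -> float:
    """Tarone–Greenland pooled neutrality index over genes."""
    num = sum(g.ds * g.pn / (g.ps + g.ds) for g in genes if g.ps + g.ds > 0)
    den = sum(g.dn * g.ps / (g.ps + g.ds) for g in genes if g.ps + g.ds > 0)
    if den == 0:
        return np.nan
    return num / den


def ni_tg(
    genes: list[MKCounts],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, tuple[float, float], float]:
    """NI_TG with a parametric bootstrap: (point, (lo, hi), p vs 1).

    Each replicate redraws every gene's four counts from independent Poisson
    distributions at the observed values and recomputes the pooled index;
    the CI is the 2.5/97.5 percentile band and p is twice the smaller tail
    fraction of replicates across 1 (capped at 1).
    """
    if not any(g.ps + g.ds > 0 for g in genes):
        raise ValueError("need at least one gene with Ps + Ds > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    point = ni_tg_point(genes)
    counts = np.array([[g.dn, g.ds, g.pn, g.ps] for g in genes], dtype=float)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        sim = rng.poisson(counts)
        dn, ds, pn, ps = sim[:, 0], sim[:, 1], sim[:, 2], sim[:, 3]
        w = ps + ds
        okw = w > 0
        den = float((dn[okw] * ps[okw] / w[okw]).sum())
        num = float((ds[okw] * pn[okw] / w[okw]).sum())
        reps[b] = num / den if den > 0 else np.nan
    ok = np.isfinite(reps)
    # sparse divergence counts leave most replicates undefined; a CI or p
    # from a handful of them would be spurious
    if ok.sum() < max(50, n_boot // 10):
        return point, (np.nan, np.nan), np.nan
    lo, hi = np.percentile(reps[ok], [2.5, 97.5])
    below = float((reps[ok] < 1.0).mean())
    above = float((reps[ok] > 1.0).mean())
    p = min(1.0, 2.0 * min(below, above))
    return point, (float(lo), float(hi)), p


def dos(c: MKCounts) -> float:
    """Direction of selection Dn/(Dn+Ds) - Pn/(Pn+Ps); NaN on empty margins."""
    if c.dn + c.ds == 0 or c.pn + c.ps == 0:
        return np.nan
    return c.dn / (c.dn + c.ds) - c.pn / (c.pn + c.ps)


def mk_fisher(c: MKCounts) -> float:
    """Two-sided Fisher exact p on the 2x2 table ((Dn, Ds), (Pn, Ps))."""
    if c.dn + c.ds + c.pn + c.ps == 0:
        raise ValueError("all-zero MK table")
    _, p = stats.fisher_exact([[c.dn, c.ds], [c.pn, c.ps]])
    return float(p)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def selection_table(
    genes: list[MKCounts], alpha: float = 0.05, correct: bool = True
) -> pd.DataFrame:
    """Per-gene NI, DoS, Fisher p, BH q and the positive-selection flag.

    A gene is flagged positively selected when its (BH-corrected when
    ``correct``) Fisher p falls below alpha AND NI < 1.
    """
    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g.gene, "dn": g.dn, "ds": g.ds, "pn": g.pn, "ps": g.ps,
                "ni": neutrality_index(g), "dos": dos(g), "fisher_p": mk_fisher(g),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = _bh_adjust(df["fisher_p"].to_numpy())
        crit = df["q"] if correct else df["fisher_p"]
        df["positively_selected"] = (crit < alpha) & (df["ni"] < 1)
    return df


def compare_ni_between_groups(
    cross_morph: list[float], within_morph: list[float]
) -> float:
    """One-sided exact rank test that cross-morph NI_TG values are lower.

    Exact Mann–Whitney enumeration; suitable for the handful of species-pair
    comparisons a small radiation affords.
    """
    if not cross_morph or not within_morph:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(
        cross_morph, within_morph, alternative="less", method="exact"
    )
    return float(res.pvalue)
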