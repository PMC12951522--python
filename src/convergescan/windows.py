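"""Sliding-window diversity, divergence and cluster-separation statistics.

Windows are 0-based half-open intervals tiling each contig (default 20 kb
windows, 10 kb step). Per window this module computes

* nucleotide diversity pi per species (per-bp expected heterozygosity with
  the unbiased n/(n-1) correction, summed over SNPs),
* Dxy, the average per-bp between-species distance, and the net divergence
  Da = Dxy - (piA + piB)/2, which subtracts shared ancestral polymorphism,
* the cluster separation score (CSS): individuals are placed by principal
  coordinates of an allele-sharing distance matrix and the mean between-morph
  distance is contrasted against the size-weighted mean within-morph
  distance, with significance from permuting morph labels,
* the frequency-based ABBA-BABA D statistic and its conservative Dmin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frequencies import AlleleFrequencyTable
from .panel import SpeciesPanel
from .variants import MISSING, GenotypeMatrix, VariantTable


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    @property
    def size(self) -> int:
        return self.end - self.start


def make_windows(
    contig_lengths: dict[str, int], size: int = 20_000, step: int = 10_000
) -> list[Window]:
    """Tile each contig with sliding windows; the last window is truncated."""
    if step <= 0 or size <= 0:
        raise ValueError("size and step must be positive")
    if size < step:
        raise ValueError("size must be >= step")
    out: list[Window] = []
    for chrom, length in contig_lengths.items():
        for start in range(0, length, step):
            out.append(Window(chrom, start, min(start + size, length)))
    return out


def _site_window_map(
    vt: VariantTable, windows: list[Window]
) -> list[np.ndarray]:
    """Indices of variants falling in each window (1-based pos -> half-open)."""
    pos0 = vt.pos - 1
    chrom = vt.chrom
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        by_chrom[c] = np.flatnonzero(chrom == c)
    out = []
    for w in windows:
        idx = by_chrom.get(w.chrom, np.array([], dtype=int))
        p = pos0[idx]
        out.append(idx[(p >= w.start) & (p < w.end)])
    return out


def _site_pi(calls_sub: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2*n_ref*n_alt/(n*(n-1)) for one species.

    calls_sub: (sites, individuals) dosages. Sites with <2 called copies get 0
    contribution (skipped).
    """
    called = calls_sub != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, calls_sub, 0).sum(axis=1)
    ref = n - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * ref * alt / (n * np.maximum(n - 1, 1)), 0.0)
    return pi


def window_diversity(
    gt: GenotypeMatrix,
    vt: VariantTable,
    panel: SpeciesPanel,
    windows: list[Window],
    exclude_indels: bool = True,
) -> pd.DataFrame:
    """Per-window, per-species pi (per bp). Indels are excluded by default."""
    usable = vt.is_snp if exclude_indels else np.ones(len(vt), dtype=bool)
    site_pi = {
        sp: _site_pi(gt.calls[:, panel.sample_indices(sp)]) * usable
        for sp in panel.species()
    }
    rows = []
    for w, idx in zip(windows, _site_window_map(vt, windows)):
        rec = {"chrom": w.chrom, "start": w.start, "end": w.end,
               "n_sites": int(usable[idx].sum())}
        for sp in panel.species():
            rec[f"pi_{sp}"] = float(site_pi[sp][idx].sum()) / w.size
        rows.append(rec)
    return pd.DataFrame(rows)


def window_divergence(
    af: AlleleFrequencyTable,
    vt: VariantTable,
    windows: list[Window],
    pair: tuple[str, str],
    pi_table: pd.DataFrame,
    exclude_indels: bool = True,
) -> pd.DataFrame:
    """Per-window Dxy and net divergence Da = Dxy - (piA + piB)/2."""
    a, b = pair
    if a == b:
        raise ValueError("pair species must differ")
    pa, pb = af.col(a), af.col(b)
    usable = (vt.is_snp if exclude_indels else np.ones(len(vt), bool)) & \
        np.isfinite(pa) & np.isfinite(pb)
    site_dxy = np.where(usable, pa * (1 - pb) + pb * (1 - pa), 0.0)
    rows = []
    for k, (w, idx) in enumerate(zip(windows, _site_window_map(vt, windows))):
        dxy = float(site_dxy[idx].sum()) / w.size
        pi_a = float(pi_table.loc[k, f"pi_{a}"])
        pi_b = float(pi_table.loc[k, f"pi_{b}"])
        rows.append(
            {"chrom": w.chrom, "start": w.start, "end": w.end,
             "dxy": dxy, "da": dxy - (pi_a + pi_b) / 2.0}
        )
    return pd.DataFrame(rows)


def da_outlier_windows(da: np.ndarray, quantile: float = 0.95) -> np.ndarray:
    """Indices of windows with Da strictly above the empirical quantile.

    The strict comparison means an all-tied input yields no outliers.
    """
    da = np.asarray(da, dtype=float)
    ok = np.isfinite(da)
    if not ok.any():
        raise ValueError("no window with defined Da")
    cut = np.quantile(da[ok], quantile)
    return np.flatnonzero(ok & (da > cut))


def outlier_overlap_test(
    set_a: np.ndarray,
    set_b: np.ndarray,
    n_total: int,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[int, float, float]:
    """Observed vs chance overlap of two window sets in a universe of n_total.

    Returns (observed, expected, p) where expected = |A||B|/n_total (the
    hypergeometric mean) and p is one-sided (excess overlap) from permuting
    the labels of set A over the universe, with the add-one estimator.
    """
    set_a = np.asarray(set_a)
    set_b = np.asarray(set_b)
    if n_total < len(set_a) or n_total < len(set_b):
        raise ValueError("universe smaller than a set")
    rng = rng or np.random.default_rng()
    in_b = np.zeros(n_total, dtype=bool)
    in_b[set_b] = True
    observed = int(in_b[set_a].sum())
    expected = len(set_a) * len(set_b) / n_total
    hits = 0
    for _ in range(n_perm):
        perm = rng.choice(n_total, size=len(set_a), replace=False)
        if int(in_b[perm].sum()) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, expected, p


def allele_sharing_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise distance 1 - shared-allele proportion between individuals.

    For two diploid dosages g, h at a site both called, the shared-allele
    proportion is 1 - |g - h|/2; the distance averages its complement over
    sites called in both individuals. Pairs with no jointly called site get
    distance NaN.
    """
    called = (calls != MISSING).astype(np.float64)
    # |g - h| over dosages in {0,1,2} decomposes over value indicators, which
    # turns the masked pairwise mean into a handful of matrix products.
    ind = [((calls == v) & (calls != MISSING)).astype(np.float64) for v in (0, 1, 2)]
    num = np.zeros((calls.shape[1], calls.shape[1]))
    for u in range(3):
        for v in range(3):
            if u != v:
                num += abs(u - v) * (ind[u].T @ ind[v])
    den = called.T @ called  # jointly called site counts
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / (2.0 * np.maximum(den, 1)), np.nan)
    np.fill_diagonal(d, 0.0)
    return d


def _pcoa_coords(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical MDS: top-k principal coordinates of a distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def _css_statistic(coords: np.ndarray, grp1: np.ndarray, grp2: np.ndarray) -> float:
    """Mean between-group distance minus size-weighted mean within-group."""
    def mean_pair(idx_a, idx_b):
        return float(
            np.mean(
                np.linalg.norm(
                    coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=-1
                )
            )
        )

    def mean_within(idx):
        if len(idx) < 2:
            return 0.0
        sub = coords[idx]
        dd = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        iu = np.triu_indices(len(idx), 1)
        return float(dd[iu].mean())

    m, n = len(grp1), len(grp2)
    between = mean_pair(grp1, grp2)
    within = (m * mean_within(grp1) + n * mean_within(grp2)) / (m + n)
    return between - within


@dataclass
class CSSRecord:
    window: Window
    css: float
    p_perm: float
    n_perm: int
    defined: bool = True


def css(
    gt: GenotypeMatrix,
    vt: VariantTable,
    window: Window,
    panel: SpeciesPanel,
    n_perm: int = 199,
    min_snps: int = 5,
    use_mds: bool = True,
    rng: np.random.Generator | None = None,
) -> CSSRecord:
    """Cluster separation score between morphotypes for one window.

    Distances come from allele sharing over the window's SNPs; individuals
    are projected onto the first two principal coordinates (or the raw
    distance matrix is used when ``use_mds`` is off). The permutation p uses
    the add-one estimator over random reassignments of individuals to groups
    of the observed sizes, so the smallest achievable p is 1/(n_perm+1).
    """
    rng = rng or np.random.default_rng()
    idx = _site_window_map(vt, [window])[0]
    idx = idx[vt.is_snp[idx]]
    if len(idx) < min_snps:
        return CSSRecord(window, np.nan, np.nan, n_perm, defined=False)
    slender = np.array(panel.morph_members("slender"))
    stout = np.array(panel.morph_members("stout"))
    members = np.concatenate([slender, stout])
    calls = gt.calls[np.ix_(idx, members)]
    d = allele_sharing_distance(calls)
    if np.isnan(d).any():
        d = np.nan_to_num(d, nan=float(np.nanmax(d)) if np.isfinite(np.nanmax(d)) else 0.0)
    m = len(slender)
    grp1 = np.arange(m)
    grp2 = np.arange(m, m + len(stout))

    if use_mds:
        coords = _pcoa_coords(d, 2)
        stat = lambda g1, g2: _css_statistic(coords, g1, g2)  # noqa: E731
    else:
        def stat(g1, g2, _d=d):
            between = float(_d[np.ix_(g1, g2)].mean())
            def win(idx_):
                if len(idx_) < 2:
                    return 0.0
                iu = np.triu_indices(len(idx_), 1)
                return float(_d[np.ix_(idx_, idx_)][iu].mean())
            return between - (len(g1) * win(g1) + len(g2) * win(g2)) / (len(g1) + len(g2))

    observed = stat(grp1, grp2)
    hits = 0
    labels = np.arange(len(members))
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if stat(perm[:m], perm[m:]) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return CSSRecord(window, observed, p, n_perm)


@dataclass
class DStatRecord:
    taxa: tuple[str, str, str, str]
    d: float
    dmin: float
    abba: float
    baba: float
    defined: bool = True


def patterson_d(
    af: AlleleFrequencyTable, taxa: tuple[str, str, str, str]
) -> DStatRecord:
    """Frequency-based ABBA-BABA D for (P1, P2, P3, outgroup), plus Dmin.

    ABBA = sum (1-p1) p2 p3 (1-p4), BABA = sum p1 (1-p2) p3 (1-p4),
    D = (ABBA - BABA)/(ABBA + BABA). Dmin is the minimum |D| over the three
    arrangements of the ingroup trio with the outgroup fixed — a conservative
    signal of gene flow that no tree topology can explain away.
    """
    if len(set(taxa)) != 4:
        raise ValueError("four distinct taxa required")
    for t in taxa:
        if t not in af.species:
            raise ValueError(f"taxon {t!r} absent from frequency table")

    def one_d(p1, p2, p3, p4):
        ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(p4)
        abba = float(((1 - p1) * p2 * p3 * (1 - p4))[ok].sum())
        baba = float((p1 * (1 - p2) * p3 * (1 - p4))[ok].sum())
        if abba + baba == 0:
            return np.nan, abba, baba
        return (abba - baba) / (abba + baba), abba, baba

    p = {t: af.col(t) for t in taxa}
    t1, t2, t3, t4 = taxa
    d, abba, baba = one_d(p[t1], p[t2], p[t3], p[t4])
    ds = []
    for trio in ((t1, t2, t3), (t1, t3, t2), (t2, t3, t1)):
        dd, _, _ = one_d(p[trio[0]], p[trio[1]], p[trio[2]], p[t4])
        if np.isfinite(dd):
            ds.append(abs(dd))
    dmin = min(ds) if ds else np.nan
    return DStatRecord(taxa, d, dmin, abba, baba, defined=np.isfinite(d))
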