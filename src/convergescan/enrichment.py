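"""Over-representation analysis with a custom background, BH FDR, and the
label-reshuffle uniqueness screen.

The enrichment p for a term with K background genes, against a query of n
genes from a background of N, is the hypergeometric upper tail
P[X >= k] with k the query/term intersection size. Only over-representation
is tested. The uniqueness screen keeps terms significant for the true
morphotype comparison but in none of the permuted-label comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TermMap:
    """Term ID -> gene set, with optional display names."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def restrict(self, background: set[str]) -> "TermMap":
        return TermMap(
            {t: g & background for t, g in self.terms.items()}, self.names
        )


def read_gmt(path) -> TermMap:
    """Read a GMT file (term <tab> description <tab> gene...)."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(parts[2:])
            names[parts[0]] = parts[1]
    return TermMap(terms, names)


def write_gmt(tm: TermMap, path) -> None:
    with open(path, "w") as fh:
        for t, genes in tm.terms.items():
            name = tm.names.get(t, t)
            fh.write("\t".join([t, name, *sorted(genes)]) + "\n")


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def ora(
    query: set[str],
    background: set[str],
    terms: TermMap,
    alpha: float = 0.05,
    min_term_size: int = 1,
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query gene set.

    Returns one row per tested term with k, K, n, N, p, BH q and the
    significance flag at ``alpha`` on q. The query must be a subset of the
    background; terms are restricted to background genes before testing.
    """
    if not background:
        raise ValueError("background gene set is empty")
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    restricted = terms.restrict(background)
    big_n = len(background)
    n = len(query)
    rows = []
    for term, genes in restricted.terms.items():
        big_k = len(genes)
        if big_k < min_term_size:
            continue
        if max_term_size is not None and big_k > max_term_size:
            continue
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "name": terms.names.get(term, term),
                     "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = _bh(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
        df = df.sort_values("p").reset_index(drop=True)
    return df


def significant_terms(result: pd.DataFrame) -> set[str]:
    if not len(result):
        return set()
    return set(result.loc[result["significant"], "term"])


def unique_terms(
    true_result: pd.DataFrame, permuted_results: list[pd.DataFrame]
) -> set[str]:
    """Terms significant in the true comparison and in no permuted one."""
    uniq = significant_terms(true_result)
    for perm in permuted_results:
        uniq -= significant_terms(perm)
    return uniq
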