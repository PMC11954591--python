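"""Preranked gene-set enrichment with the classic (unweighted) statistic,
and hypergeometric overrepresentation analysis (ORA).

Ranking follows the two-group recipe: genes whose copy number associates
positively with the phenotype occupy the top of the list ordered by
ascending p, negatively associated genes the bottom ordered by descending p.
This is the total order induced by the signed score ``sign(estimate) *
-log10(p)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneSetCollection
from .screens import adjust_pvalues

__all__ = [
    "RankedList",
    "build_ranked_list",
    "classic_enrichment_score",
    "gsea_preranked",
    "ora_test",
]


@dataclass
class RankedList:
    """Genes ordered by the signed -log10(p) association score."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def build_ranked_list(
    screen: pd.DataFrame, annotation: dict[str, tuple[str, ...]]
) -> RankedList:
    """Build the ranked gene list from a per-orthogroup screen table.

    Each orthogroup's symbols inherit its (estimate, p); a symbol annotated
    to several orthogroups keeps its smallest-p row.  Ties in the signed
    score break by larger |estimate| first, then by symbol.
    """
    rows = screen[screen.get("testable", True).astype(bool)] if "testable" in screen else screen
    best: dict[str, tuple[float, float]] = {}
    for _, row in rows.iterrows():
        for sym in annotation.get(row["unit_id"], ()):
            p, est = float(row["p"]), float(row["estimate"])
            if sym not in best or p < best[sym][0]:
                best[sym] = (p, est)
    if not best:
        raise ValueError("no annotated genes among screened orthogroups")
    tiny = np.nextafter(0.0, 1.0)
    records = []
    for sym, (p, est) in best.items():
        if p == 0.0:
            warnings.warn(
                f"p-value 0 for gene {sym!r}; replaced by the smallest "
                "positive float before log",
                UserWarning,
                stacklevel=2,
            )
            p = tiny
        sign = 1.0 if est >= 0 else -1.0
        records.append((sym, sign * -np.log10(p), abs(est)))
    records.sort(key=lambda r: (-r[1], -r[2], r[0]))
    genes = [r[0] for r in records]
    scores = np.array([r[1] for r in records])
    return RankedList(genes=genes, scores=scores)


def classic_enrichment_score(n: int, hit_positions: np.ndarray) -> float:
    """Classic (unweighted) enrichment score.

    The running sum gains ``1/k`` at each of the ``k`` hit positions and
    loses ``1/(n - k)`` at misses; the ES is the maximum deviation from zero
    (signed).
    """
    k = len(hit_positions)
    if k == 0 or k >= n:
        raise ValueError(f"need 1 <= hits < list size, got {k} of {n}")
    steps = np.full(n, -1.0 / (n - k))
    steps[hit_positions] = 1.0 / k
    running = np.cumsum(steps)
    hi, lo = running.max(), running.min()
    return float(hi if hi >= -lo else lo)


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    min_size: int = 1,
) -> pd.DataFrame:
    """Preranked GSEA with the classic statistic and gene-label permutation.

    For each set overlapping the list, the ES is computed on the observed
    hit positions; significance comes from ``n_perm`` random draws of
    equally sized hit sets (p with the add-one convention, one-sided within
    the sign of the observed ES).  NES divides ES by the mean |permuted ES|
    of the same sign.  BH adjustment is applied separately within positive
    and negative ES groups.
    """
    n = len(ranked)
    position = {g: i for i, g in enumerate(ranked.genes)}
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.sets.items():
        hits = np.array(sorted(position[g] for g in set(members) if g in position))
        if len(hits) < min_size or len(hits) == 0:
            continue
        if len(hits) >= n:
            raise ValueError(
                f"set {name!r} covers the whole ranked list; ES undefined"
            )
        es = classic_enrichment_score(n, hits)
        k = len(hits)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_hits = rng.choice(n, size=k, replace=False)
            perm_es[b] = classic_enrichment_score(n, perm_hits)
        if es >= 0:
            same = perm_es[perm_es >= 0]
            extreme = int(np.sum(same >= es))
        else:
            same = perm_es[perm_es < 0]
            extreme = int(np.sum(same <= es))
        p = (extreme + 1) / (len(same) + 1)
        denom = float(np.mean(np.abs(same))) if len(same) else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append(
            {
                "set": name,
                "size": k,
                "ES": es,
                "NES": nes,
                "p": p,
                "direction": "pos" if es >= 0 else "neg",
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adjusted"] = np.nan
    for direction in ("pos", "neg"):
        mask = (table["direction"] == direction).to_numpy()
        if mask.any():
            table.loc[mask, "p_adjusted"] = adjust_pvalues(
                table.loc[mask, "p"].to_numpy(), "BH"
            )
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def ora_test(
    significant: set[str],
    background: set[str],
    sets: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation test per gene set.

    ``significant`` must be a subset of ``background``; the universe is the
    background (genes mapped to tested orthogroups, not the whole genome).
    One-sided upper-tail p; BH across sets; ``significant_fdr`` flags sets
    at the given FDR.
    """
    significant = set(significant)
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    if not significant <= background:
        extra = sorted(significant - background)[:5]
        raise ValueError(f"significant genes outside background: {extra}")
    N = len(background)
    n_sig = len(significant)
    rows = []
    for name, members in sets.sets.items():
        in_bg = set(m for m in members) & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & significant)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sig))
        expected = K * n_sig / N
        rows.append(
            {
                "set": name,
                "size_in_background": K,
                "overlap": k,
                "fold": (k / expected) if expected > 0 else np.nan,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adjusted"] = adjust_pvalues(table["p"].to_numpy(), "BH")
    table["significant_fdr"] = table["p_adjusted"] < fdr_threshold
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)
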