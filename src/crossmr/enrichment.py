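"""Gene-set enrichment against ranked signatures.

Weighted Kolmogorov-Smirnov running-sum enrichment (GSEA-style), with the
normalized enrichment score (NES) and p-value estimated from gene
permutations: random query sets of identical size drawn from the
signature's gene universe.  The NES is a permutation z-score,
``(ES_obs - mean_null) / sd_null``; p-values are two-sided with the add-one
correction, so the smallest reportable p is ``1 / (n_perm + 1)``.

The running sum walks the ranking from top to bottom: a query gene ("hit")
at rank *i* adds ``|score_i|^w / NR`` (``NR`` the sum over all hits), any
other gene subtracts ``1 / (N - |S|)``.  The enrichment score is the
running-sum value of largest absolute magnitude; the query genes at or
before (positive ES) / at or after (negative ES) that extremum form the
leading edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentError",
    "DegenerateNullError",
    "EnrichmentResult",
    "enrichment_score",
    "leading_edge",
    "permutation_nes",
    "two_tail_gsea",
    "leading_edge_overlap_test",
    "pathway_enrichment",
]


class EnrichmentError(ValueError):
    """Degenerate enrichment instance (empty/complete overlap, tiny universe)."""


class DegenerateNullError(EnrichmentError):
    """The permutation null has zero spread; NES is undefined."""


@dataclass(frozen=True)
class EnrichmentResult:
    """One query set scored against one signature."""

    es: float
    nes: float
    p: float
    leading_edge: frozenset
    n_perm: int
    running_sum: np.ndarray | None = None


def _hit_mask(sig: GeneSignature, query: Iterable[str]) -> np.ndarray:
    return np.isin(sig.genes, np.asarray(sorted(query), dtype=str), assume_unique=False)


def _hit_weights(scores: np.ndarray, weight_exponent: float) -> np.ndarray:
    return np.abs(scores) ** weight_exponent


def enrichment_score(
    sig: GeneSignature,
    query: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, int]:
    """Running-sum enrichment score of ``query`` in ``sig``.

    Returns ``(ES, running_sum, extremum_index)`` where ``extremum_index``
    is the 1-based rank position of the extremum (first occurrence on ties).
    """
    hit = _hit_mask(sig, query)
    n = len(sig)
    k = int(hit.sum())
    if k == 0:
        raise EnrichmentError("query set is disjoint from the signature")
    if k == n:
        raise EnrichmentError("query set covers the entire signature")
    w = _hit_weights(sig.scores, weight_exponent)
    hw = np.where(hit, w, 0.0)
    nr = hw.sum()
    if nr <= 0:  # all hit scores exactly zero: fall back to unweighted hits
        hw = hit.astype(float)
        nr = float(k)
    inc = hw / nr
    inc[~hit] = -1.0 / (n - k)
    rs = np.cumsum(inc)
    idx = int(np.argmax(np.abs(rs)))
    return float(rs[idx]), rs, idx + 1


def leading_edge(
    sig: GeneSignature,
    query: Iterable[str],
    weight_exponent: float = 1.0,
) -> frozenset:
    """Query genes carrying the enrichment (at/before the extremum for
    positive ES, at/after it for negative ES)."""
    es, _, xi = enrichment_score(sig, query, weight_exponent)
    hit = _hit_mask(sig, query)
    if es >= 0:
        sel = hit[:xi].nonzero()[0]
        genes = sig.genes[:xi][sel]
    else:
        sel = hit[xi - 1 :].nonzero()[0]
        genes = sig.genes[xi - 1 :][sel]
    return frozenset(genes.tolist())


def _es_from_hit_ranks(
    ranks: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit placements at once.

    ``ranks``: (m, k) 1-based hit rank positions, ascending within each row;
    ``weights``: matching non-negative hit weights.  Exploits that the
    running sum is piecewise linear with extrema only at hit positions (and
    immediately before them), so only O(k) candidates per row are examined.
    """
    m, k = ranks.shape
    wsum = weights.sum(axis=1, keepdims=True)
    zero = wsum[:, 0] <= 0
    if zero.any():
        weights = weights.copy()
        weights[zero] = 1.0
        wsum = weights.sum(axis=1, keepdims=True)
    cw = np.cumsum(weights, axis=1) / wsum
    miss = 1.0 / (n - k)
    i = np.arange(1, k + 1)
    at_hit = cw - (ranks - i) * miss          # running sum at each hit
    before = at_hit - weights / wsum          # running sum just before it
    cand = np.empty((m, 2 * k))
    cand[:, 0::2] = before
    cand[:, 1::2] = at_hit
    best = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(m), best]


def _random_hit_positions(
    rng: np.random.Generator, n_perm: int, n: int, k: int
) -> np.ndarray:
    """(n_perm, k) distinct 0-based rank positions per row, sorted."""
    u = rng.random((n_perm, n))
    pos = np.argpartition(u, k - 1, axis=1)[:, :k] if k < n else np.tile(np.arange(n), (n_perm, 1))
    pos.sort(axis=1)
    return pos


def permutation_nes(
    sig: GeneSignature,
    query: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    keep_running_sum: bool = False,
) -> EnrichmentResult:
    """Gene-permutation NES and p for one query set.

    The null draws ``n_perm`` random query sets of identical size uniformly
    without replacement from the signature's genes.  NES is the z-score of
    the observed ES against that null; p is two-sided with the add-one rule.
    """
    es, rs, xi = enrichment_score(sig, query, weight_exponent)
    hit = _hit_mask(sig, query)
    k = int(hit.sum())
    n = len(sig)
    if es >= 0:
        le = frozenset(sig.genes[:xi][hit[:xi]].tolist())
    else:
        le = frozenset(sig.genes[xi - 1 :][hit[xi - 1 :]].tolist())
    rng = np.random.default_rng(seed)
    w = _hit_weights(sig.scores, weight_exponent)
    pos = _random_hit_positions(rng, n_perm, n, k)
    null = _es_from_hit_ranks(pos + 1, w[pos], n)
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError("permutation null has zero variance")
    nes = (es - float(null.mean())) / sd
    p = (1 + int(np.count_nonzero(np.abs(null) >= abs(es)))) / (n_perm + 1)
    return EnrichmentResult(es, nes, p, le, n_perm, rs if keep_running_sum else None)


def two_tail_gsea(
    reference: GeneSignature,
    query: GeneSignature,
    top_n: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Signature-versus-signature GSEA with separate up/down query tails.

    The query's ``top_n`` highest-scoring genes form the positive query set
    and its ``top_n`` lowest-scoring genes the negative set; each is scored
    against the reference signature restricted to the shared gene universe.
    A concordant pair of signatures yields positive NES for the first
    result and negative NES for the second.
    """
    shared = reference.gene_set() & query.gene_set()
    if len(shared) < 10:
        raise EnrichmentError(
            f"signatures share only {len(shared)} genes; need >= 10"
        )
    if len(shared) < 2 * top_n:
        new_top = len(shared) // 2
        logger.warning(
            "two_tail_gsea: shared universe (%d) below 2*top_n; reducing "
            "top_n %d -> %d", len(shared), top_n, new_top,
        )
        top_n = new_top
    ref = reference.restrict(shared)
    q = query.restrict(shared)
    pos_set = frozenset(q.genes[:top_n].tolist())
    neg_set = frozenset(q.genes[-top_n:].tolist())
    rng = np.random.default_rng(seed)
    s_pos, s_neg = (int(s) for s in rng.integers(2**31, size=2))
    res_pos = permutation_nes(ref, pos_set, n_perm, s_pos, weight_exponent)
    res_neg = permutation_nes(ref, neg_set, n_perm, s_neg, weight_exponent)
    return res_pos, res_neg


def leading_edge_overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    denominator: str = "min",
) -> tuple[float, float, float]:
    """Overlap fraction of two gene sets plus a 2x2 chi-square over the universe.

    The overlap fraction divides |A ∩ B| by the smaller set (default) or by
    the union.  The chi-square uses the membership contingency table over
    the universe without continuity correction.
    """
    uni = frozenset(universe)
    if not uni:
        raise EnrichmentError("empty universe")
    a = frozenset(set_a) & uni
    b = frozenset(set_b) & uni
    if not a or not b:
        raise EnrichmentError("both sets must be nonempty within the universe")
    inter = len(a & b)
    if denominator == "min":
        frac = inter / min(len(a), len(b))
    elif denominator == "union":
        frac = inter / len(a | b)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    table = np.array(
        [
            [inter, len(a) - inter],
            [len(b) - inter, len(uni) - len(a | b)],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return frac, float(chi2), float(p)


def pathway_enrichment(
    sig: GeneSignature,
    gene_sets: Mapping[str, frozenset],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    p_threshold: float = 0.05,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Permutation GSEA of every gene set in a collection against one signature.

    Sets overlapping the signature by fewer than ``min_overlap`` genes are
    skipped with a warning.  The returned table flags each set by enrichment
    sign and by ``p < p_threshold``.
    """
    sig_genes = sig.gene_set()
    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = 0
    for name in sorted(gene_sets):
        genes = frozenset(gene_sets[name])
        overlap = genes & sig_genes
        child = int(rng.integers(2**31))
        if len(overlap) < min_overlap or len(overlap) >= len(sig_genes):
            n_skipped += 1
            continue
        res = permutation_nes(sig, overlap, n_perm, child, weight_exponent)
        rows.append(
            {
                "gene_set": name,
                "n_genes": len(genes),
                "n_overlap": len(overlap),
                "es": res.es,
                "nes": res.nes,
                "p": res.p,
                "direction": "positive" if res.nes >= 0 else "negative",
                "significant": res.p < p_threshold,
                "leading_edge": ",".join(sorted(res.leading_edge)),
            }
        )
    if n_skipped:
        logger.warning(
            "pathway_enrichment: skipped %d set(s) with < %d overlapping genes",
            n_skipped, min_overlap,
        )
    if not rows:
        raise EnrichmentError("no gene set overlaps the signature")
    return pd.DataFrame(rows).set_index("gene_set")
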