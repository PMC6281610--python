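"""Ranked differential-expression signatures.

A *signature* is the universal currency between pipeline stages: an ordered
gene -> score map, where the score is a signed statistic (Welch t, or a
cohort z-score for per-sample signatures).  Ordering is always descending by
score with ties broken lexicographically by gene id, so every ranking is
total and reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "OrthologMap",
    "SignatureError",
    "welch_t_signature",
    "humanize_signature",
    "single_sample_signatures",
]


class SignatureError(ValueError):
    """A signature could not be built as requested (size, overlap, ...)."""


def _order(genes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Indices sorting descending by score, ties lexicographic by gene id."""
    return np.lexsort((genes, -scores))


@dataclass(frozen=True)
class GeneSignature:
    """Genes ranked by a signed differential statistic.

    Attributes
    ----------
    genes : ndarray of str
        Gene ids in rank order (highest score first).
    scores : ndarray of float
        Signed scores aligned with ``genes``; always finite.
    pvalues : ndarray of float, optional
        Per-gene two-sided p-values aligned with ``genes`` (carried as
        metadata; the score, not the p-value, drives every ranking).
    metadata : dict
        Provenance: test name, group sizes, et cetera.
    """

    genes: np.ndarray
    scores: np.ndarray
    pvalues: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls,
        genes: Iterable[str],
        scores: Iterable[float],
        pvalues: Iterable[float] | None = None,
        **metadata,
    ) -> "GeneSignature":
        """Build a signature, imposing the canonical ordering."""
        genes = np.asarray(list(genes), dtype=str)
        scores = np.asarray(list(scores), dtype=float)
        if genes.size != scores.size:
            raise SignatureError("genes and scores differ in length")
        if genes.size == 0:
            raise SignatureError("empty signature")
        if np.unique(genes).size != genes.size:
            raise SignatureError("duplicate gene ids in signature")
        if not np.all(np.isfinite(scores)):
            raise SignatureError("signature scores must be finite")
        order = _order(genes, scores)
        pv = None
        if pvalues is not None:
            pv = np.asarray(list(pvalues), dtype=float)[order]
        return cls(genes[order], scores[order], pv, dict(metadata))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], **metadata) -> "GeneSignature":
        items = list(mapping.items())
        return cls.from_scores([g for g, _ in items], [s for _, s in items], **metadata)

    def __len__(self) -> int:
        return int(self.genes.size)

    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes.tolist())

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes, name="score")

    def score_of(self, gene: str) -> float:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return float(self.scores[idx[0]])

    def restrict(self, genes: Iterable[str]) -> "GeneSignature":
        """Signature restricted to ``genes`` (re-ranked within the subset)."""
        keep = frozenset(genes)
        mask = np.fromiter((g in keep for g in self.genes), bool, len(self))
        if not mask.any():
            raise SignatureError("restriction leaves an empty signature")
        pv = self.pvalues[mask] if self.pvalues is not None else None
        return GeneSignature(self.genes[mask], self.scores[mask], pv, dict(self.metadata))

    def negated(self) -> "GeneSignature":
        return GeneSignature.from_scores(self.genes, -self.scores, **self.metadata)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene": self.genes, "score": self.scores})
        if self.pvalues is not None:
            df["p"] = self.pvalues
        return df


@dataclass(frozen=True)
class OrthologMap:
    """Source -> target gene mapping (e.g., mouse symbols to human orthologs).

    One-to-many entries are allowed (a source gene with two co-orthologs
    appears with a multi-element target tuple); target sets are never empty.
    """

    mapping: dict

    def __post_init__(self):
        for src, dsts in self.mapping.items():
            if len(dsts) == 0:
                raise ValueError(f"empty ortholog target set for {src!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        out: dict[str, tuple[str, ...]] = {}
        for src, dst in pairs:
            out[src] = out.get(src, ()) + (dst,)
        return cls(out)

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def targets(self, gene: str) -> tuple[str, ...]:
        return self.mapping[gene]

    def pairs(self) -> list[tuple[str, str]]:
        return [(s, d) for s in sorted(self.mapping) for d in self.mapping[s]]


def welch_t_signature(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    min_n: int = 5,
) -> GeneSignature:
    """Two-sample two-tailed Welch *t* signature between two phenotype groups.

    Scores are the unequal-variance t statistic with ``group_b - group_a``
    in the numerator, so positive scores mark genes up in ``group_b``.
    Genes whose statistic is undefined (zero variance in both groups) are
    dropped with a logged warning.  Each group must contribute at least
    ``min_n`` samples for the statistic to be estimable with any stability.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    present = set(labels.unique())
    for g in (group_a, group_b):
        if g not in present:
            raise KeyError(f"unknown group label {g!r}")
    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    missing = [c for c in list(cols_a) + list(cols_b) if c not in matrix.columns]
    if missing:
        raise KeyError(f"labeled samples absent from matrix: {missing[:5]}")
    if len(cols_a) < min_n or len(cols_b) < min_n:
        raise SignatureError(
            f"group sizes {len(cols_a)}/{len(cols_b)} below minimum {min_n}"
        )
    A = matrix[cols_a].to_numpy(float)
    B = matrix[cols_b].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    finite = np.isfinite(t)
    if not finite.all():
        n_zero = int((~finite & (np.isnan(t))).sum())
        n_inf = int((~finite & ~np.isnan(t)).sum())
        if n_zero:
            logger.warning(
                "welch_t_signature: dropped %d gene(s) constant in both groups "
                "with equal means (t undefined)", n_zero,
            )
        if n_inf:
            logger.warning(
                "welch_t_signature: dropped %d gene(s) with zero variance in "
                "both groups but unequal means (infinite t)", n_inf,
            )
    genes = matrix.index.to_numpy(str)[finite]
    return GeneSignature.from_scores(
        genes,
        t[finite],
        pvalues=p[finite],
        test="welch_t",
        group_a=group_a,
        group_b=group_b,
        n_a=int(len(cols_a)),
        n_b=int(len(cols_b)),
    )


def humanize_signature(sig: GeneSignature, omap: OrthologMap) -> GeneSignature:
    """Translate a signature into ortholog gene space.

    Every mapped target gene inherits its source gene's score; when several
    source genes collapse onto one target, the score of largest absolute
    value wins (ties resolved toward the lexicographically smallest source).
    Unmapped source genes are dropped; drop/collapse counts are logged.
    """
    if len(omap) == 0:
        raise SignatureError("empty ortholog map")
    chosen: dict[str, tuple[float, float | None]] = {}
    n_dropped = 0
    n_collapsed = 0
    order = np.argsort(sig.genes)  # lexicographic pass for deterministic ties
    for i in order:
        src = sig.genes[i]
        if src not in omap:
            n_dropped += 1
            continue
        score = float(sig.scores[i])
        pv = float(sig.pvalues[i]) if sig.pvalues is not None else None
        for dst in omap.targets(src):
            if dst in chosen:
                n_collapsed += 1
                if abs(score) > abs(chosen[dst][0]):
                    chosen[dst] = (score, pv)
            else:
                chosen[dst] = (score, pv)
    if not chosen:
        raise SignatureError("signature and ortholog map share no genes")
    logger.info(
        "humanize_signature: %d source gene(s) unmapped, %d collision(s) "
        "collapsed by max |score|; %d genes out", n_dropped, n_collapsed, len(chosen),
    )
    genes = sorted(chosen)
    pvals = None
    if sig.pvalues is not None:
        pvals = [chosen[g][1] for g in genes]
    out = GeneSignature.from_scores(
        genes, [chosen[g][0] for g in genes], pvalues=pvals, **sig.metadata
    )
    return out


def single_sample_signatures(matrix: pd.DataFrame) -> dict[str, GeneSignature]:
    """Per-sample z-score signatures against the cohort.

    For gene *i* and sample *j*: ``z_ij = (x_ij - mean_i) / sd_i`` with the
    mean and sd (n-1 denominator) taken over the whole cohort.  Genes with
    zero cohort variance are dropped with a warning.  Requires >= 3 samples.
    """
    if matrix.shape[1] < 3:
        raise SignatureError("per-sample signatures need at least 3 samples")
    X = matrix.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.warning(
            "single_sample_signatures: dropped %d constant gene(s)",
            int((~keep).sum()),
        )
        if not keep.any():
            raise SignatureError("all genes constant across the cohort")
    Z = (X[keep] - mu[keep]) / sd[keep]
    genes = matrix.index.to_numpy(str)[keep]
    return {
        sample: GeneSignature.from_scores(genes, Z[:, j], test="cohort_z", sample=sample)
        for j, sample in enumerate(matrix.columns)
    }
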