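"""Master-regulator activity inference and cross-species integration.

Differential activity of a regulator is the enrichment of its regulon in a
ranked signature, with repressed targets handled by a two-tail
mode-adjustment: every negative target's signature score is negated, the
signature re-ranked, and the combined target set scored by the weighted
running-sum statistic.  A regulator whose positive targets sit among the
overexpressed genes and/or whose negative targets sit among the
underexpressed genes therefore scores positive (active); the converse
scores negative (repressed).

Significance comes from gene permutations that preserve each regulon's
(n_pos, n_neg) split: random target placements with random mode
assignments.  The null is sign-symmetrized (each drawn placement
contributes both +ES and -ES, which merely re-states that activity sign is
arbitrary under the null), giving a mean-zero null, ``NES = ES / RMS(null)``
and exact antisymmetry under mode swap.  The two-sided p-value
``(1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1)`` is unaffected by the
symmetrization.

Mouse and human activity tables are combined per regulator by Stouffer
integration of the signed NES values, ``z = (z_mouse + z_human) / sqrt(2)``,
with a two-sided normal-tail p; conserved regulators additionally agree in
activity direction.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentError, _es_from_hit_ranks, enrichment_score
from .regulons import Interactome, restrict_to_signature
from .signatures import GeneSignature, OrthologMap, single_sample_signatures

logger = logging.getLogger(__name__)

__all__ = [
    "marina_activity",
    "sample_activity_matrix",
    "stouffer_integrate",
    "filter_conserved",
    "annotation_filter",
]


def _mode_adjusted(sig: GeneSignature, negative_targets) -> GeneSignature:
    """Signature with negative-target scores negated and re-ranked."""
    neg = sorted(negative_targets)
    scores = sig.scores.copy()
    if neg:
        mask = np.isin(sig.genes, np.asarray(neg, dtype=str))
        scores[mask] = -scores[mask]
    return GeneSignature.from_scores(sig.genes, scores)


def _null_placements_random(
    rng: np.random.Generator, n_perm: int, n: int, n_pos: int, n_neg: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random (gene index, sign) placements preserving the mode split."""
    k = n_pos + n_neg
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    shuffle = rng.random(idx.shape).argsort(axis=1)
    idx = np.take_along_axis(idx, shuffle, axis=1)
    signs = np.ones(k)
    signs[n_pos:] = -1.0
    return idx, np.broadcast_to(signs, idx.shape)


def _null_placements_exhaustive(
    n: int, n_pos: int, n_neg: int
) -> tuple[np.ndarray, np.ndarray]:
    """Every target placement and mode assignment on a small universe."""
    k = n_pos + n_neg
    idx_rows = []
    sign_rows = []
    for subset in itertools.combinations(range(n), k):
        subset = np.array(subset)
        for pos_positions in itertools.combinations(range(k), n_pos):
            signs = -np.ones(k)
            signs[list(pos_positions)] = 1.0
            idx_rows.append(subset)
            sign_rows.append(signs)
    return np.array(idx_rows), np.array(sign_rows)


def _null_es(
    scores: np.ndarray,
    idx: np.ndarray,
    signs: np.ndarray,
    weight_exponent: float,
) -> np.ndarray:
    """ES for every placement row, by rank counting.

    For each placement the adjusted signature equals the base scores with
    the chosen genes' scores multiplied by their assigned sign; the hit
    ranks in the re-ranked list follow from counting, with no full sort:
    rank = #{non-chosen genes above} + #{chosen genes above} + 1.
    """
    n = scores.size
    base_sorted = np.sort(scores)          # ascending
    B = scores[idx]                        # chosen genes' base scores
    A = B * signs                          # their adjusted scores
    all_gt = n - np.searchsorted(base_sorted, A, side="right")
    chosen_gt = (B[:, None, :] > A[:, :, None]).sum(axis=2)
    hits_gt = (A[:, None, :] > A[:, :, None]).sum(axis=2)
    ranks = all_gt - chosen_gt + hits_gt + 1
    order = np.argsort(ranks, axis=1)
    ranks = np.take_along_axis(ranks, order, axis=1)
    weights = np.take_along_axis(np.abs(A) ** weight_exponent, order, axis=1)
    return _es_from_hit_ranks(ranks, weights, n)


def marina_activity(
    interactome: Interactome,
    sig: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 0.0,
    null: str = "permutation",
    min_regulon_size: int = 1,
) -> pd.DataFrame:
    """Differential activity (NES, p) of every regulon in a signature.

    Regulon enrichment is unweighted by default (``weight_exponent=0``):
    for a regulon query the evidence is where the targets rank, and the
    unweighted statistic avoids the heavy-tailed null that score-weighted
    hits produce on t-statistic signatures.  Set ``weight_exponent=1`` for
    the score-weighted convention.

    ``null="permutation"`` draws ``n_perm`` random placements per regulon;
    ``null="exhaustive"`` enumerates every placement (tiny universes only).
    Regulons with a degenerate null are flagged, not dropped.  Returns a
    DataFrame indexed by regulator with columns ``es``, ``nes``, ``p``,
    ``n_pos``, ``n_neg``, ``degenerate`` and ``leading_targets``.
    """
    if null not in ("permutation", "exhaustive"):
        raise ValueError(f"unknown null {null!r}")
    restricted = restrict_to_signature(interactome, sig, min_regulon_size)
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    children = master.spawn(len(restricted.regulons))
    rows = []
    n = len(sig)
    for child, reg in zip(children, restricted):
        regulon = restricted[reg]
        n_pos = len(regulon.positive)
        n_neg = len(regulon.negative)
        adjusted = _mode_adjusted(sig, regulon.negative)
        try:
            es, _, xi = enrichment_score(adjusted, regulon.targets, weight_exponent)
        except EnrichmentError:
            logger.warning("marina_activity: degenerate instance for %s", reg)
            rows.append(
                {
                    "regulator": reg, "es": 0.0, "nes": 0.0, "p": 1.0,
                    "n_pos": n_pos, "n_neg": n_neg, "degenerate": True,
                    "leading_targets": "",
                }
            )
            continue
        hit = np.isin(adjusted.genes, np.asarray(sorted(regulon.targets), dtype=str))
        if es >= 0:
            leading = frozenset(adjusted.genes[:xi][hit[:xi]].tolist())
        else:
            leading = frozenset(adjusted.genes[xi - 1:][hit[xi - 1:]].tolist())
        if null == "permutation":
            rng = np.random.default_rng(child)
            idx, signs = _null_placements_random(rng, n_perm, n, n_pos, n_neg)
        else:
            idx, signs = _null_placements_exhaustive(n, n_pos, n_neg)
        null_es = _null_es(sig.scores, idx, signs, weight_exponent)
        rms = float(np.sqrt(np.mean(null_es**2)))
        degenerate = rms == 0.0
        if degenerate:
            logger.warning("marina_activity: degenerate null for %s", reg)
            nes = 0.0
            p = 1.0
        else:
            nes = es / rms
            p = (1 + int(np.count_nonzero(np.abs(null_es) >= abs(es)))) / (
                len(null_es) + 1
            )
        rows.append(
            {
                "regulator": reg,
                "es": es,
                "nes": nes,
                "p": p,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "degenerate": degenerate,
                "leading_targets": ",".join(sorted(leading)),
            }
        )
    return pd.DataFrame(rows).set_index("regulator")


def sample_activity_matrix(
    interactome: Interactome,
    matrix: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    weight_exponent: float = 0.0,
    min_regulon_size: int = 1,
) -> pd.DataFrame:
    """Regulators x samples matrix of per-sample activity NES.

    Each sample's cohort z-score signature is scored by
    :func:`marina_activity`; degenerate entries are set to 0 (flag logged).
    """
    sigs = single_sample_signatures(matrix)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(sigs))
    columns = {}
    for child, (sample, sig) in zip(children, sigs.items()):
        table = marina_activity(
            interactome, sig, n_perm,
            seed=child, weight_exponent=weight_exponent,
            min_regulon_size=min_regulon_size,
        )
        columns[sample] = table["nes"]
    out = pd.DataFrame(columns)
    out.index.name = "regulator"
    return out


def stouffer_integrate(
    mouse: pd.DataFrame,
    human: pd.DataFrame,
    ortholog_map: OrthologMap | None = None,
) -> pd.DataFrame:
    """Combine per-species activity tables into a conserved-MR table.

    Mouse regulator ids are first translated through the ortholog map
    (one-to-many expands; several mouse regulators collapsing onto one
    human id resolve by max |NES|).  For every regulator present in both
    species: ``z_combined = (nes_mouse + nes_human) / sqrt(2)``,
    ``p_combined`` the two-sided normal tail, and ``concordant`` flags equal
    activity signs.  Rows are ordered by descending |z_combined|.
    """
    if ortholog_map is not None:
        best: dict[str, pd.Series] = {}
        for reg in sorted(mouse.index):
            if reg not in ortholog_map:
                continue
            row = mouse.loc[reg]
            for dst in ortholog_map.targets(reg):
                if dst not in best or abs(row["nes"]) > abs(best[dst]["nes"]):
                    best[dst] = row
        mouse = pd.DataFrame(best).T
        mouse.index.name = "regulator"
    common = mouse.index.intersection(human.index)
    if len(common) == 0:
        raise ValueError("no regulator common to both species")
    zm = mouse.loc[common, "nes"].astype(float)
    zh = human.loc[common, "nes"].astype(float)
    z = (zm + zh) / np.sqrt(2.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "nes_mouse": zm,
            "p_mouse": mouse.loc[common, "p"].astype(float),
            "nes_human": zh,
            "p_human": human.loc[common, "p"].astype(float),
            "z_combined": z,
            "p_combined": p,
            "concordant": np.sign(zm) * np.sign(zh) > 0,
        },
        index=common,
    )
    out.index.name = "regulator"
    return out.sort_values("z_combined", key=np.abs, ascending=False)


def filter_conserved(
    table: pd.DataFrame,
    p_threshold: float = 1e-4,
    require_concordance: bool = True,
    direction: str = "activated",
) -> pd.DataFrame:
    """Conserved-MR subset: combined p below threshold, optionally
    direction-concordant, and matching the requested activity direction
    (``activated``, ``repressed`` or ``both``)."""
    if table.empty:
        raise ValueError("empty conserved-MR table")
    if direction not in ("activated", "repressed", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    keep = table["p_combined"] < p_threshold
    if require_concordance:
        keep &= table["concordant"]
    if direction == "activated":
        keep &= table["z_combined"] > 0
    elif direction == "repressed":
        keep &= table["z_combined"] < 0
    out = table[keep]
    if out.empty:
        logger.info("filter_conserved: no regulator passes the filter")
    return out


def annotation_filter(table: pd.DataFrame, annotation) -> pd.DataFrame:
    """Rows whose regulator belongs to a user-supplied annotation gene set
    (e.g., a curated list of epigenetic regulators)."""
    ann = frozenset(annotation)
    if not ann:
        raise ValueError("empty annotation set")
    out = table[table.index.isin(ann)]
    if out.empty:
        logger.info("annotation_filter: no regulator in the annotation set")
    return out
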