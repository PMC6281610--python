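"""Regulatory networks (interactomes) consumed by master-regulator inference.

A regulon is one regulator together with its transcriptional targets, split
into positively regulated (mode +1) and repressed (mode -1) targets; an
interactome is a collection of regulons over a gene universe.  Interactomes
are inputs to this pipeline — network reverse-engineering is out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .signatures import GeneSignature, OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "Regulon",
    "Interactome",
    "InteractomeParseError",
    "read_interactome",
    "write_interactome",
    "restrict_to_signature",
    "translate_interactome",
]


class InteractomeParseError(ValueError):
    """Malformed interactome file (bad mode/weight, duplicate edge)."""


@dataclass(frozen=True)
class Regulon:
    """One regulator with signed, weighted target sets.

    ``positive`` and ``negative`` map target gene -> weight in (0, 1]; the
    two sets are disjoint and never contain the regulator itself.
    """

    regulator: str
    positive: Mapping[str, float] = field(default_factory=dict)
    negative: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(
                f"regulon {self.regulator!r}: targets in both modes: {sorted(overlap)[:3]}"
            )
        if self.regulator in self.positive or self.regulator in self.negative:
            raise ValueError(f"regulon {self.regulator!r} contains itself as a target")
        for tgt, w in list(self.positive.items()) + list(self.negative.items()):
            if not (0 < w <= 1):
                raise ValueError(
                    f"regulon {self.regulator!r}: weight {w} for {tgt!r} outside (0, 1]"
                )

    @property
    def targets(self) -> frozenset:
        return frozenset(self.positive) | frozenset(self.negative)

    @property
    def size(self) -> int:
        return len(self.positive) + len(self.negative)


class Interactome:
    """Regulator -> Regulon map over a gene universe."""

    def __init__(self, regulons: Iterable[Regulon], universe: Iterable[str]):
        self.universe = frozenset(universe)
        self.regulons: dict[str, Regulon] = {}
        for reg in regulons:
            if reg.regulator in self.regulons:
                raise ValueError(f"duplicate regulator {reg.regulator!r}")
            missing = reg.targets - self.universe
            if missing:
                raise ValueError(
                    f"regulon {reg.regulator!r} targets outside the universe: "
                    f"{sorted(missing)[:3]}"
                )
            self.regulons[reg.regulator] = reg

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self):
        return iter(sorted(self.regulons))

    def __getitem__(self, regulator: str) -> Regulon:
        return self.regulons[regulator]

    def __contains__(self, regulator: str) -> bool:
        return regulator in self.regulons

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.universe == other.universe and {
            r: (dict(v.positive), dict(v.negative)) for r, v in self.regulons.items()
        } == {
            r: (dict(v.positive), dict(v.negative)) for r, v in other.regulons.items()
        }

    def summary(self) -> dict:
        sizes = sorted(r.size for r in self.regulons.values())
        return {
            "n_regulators": len(self.regulons),
            "n_genes": len(self.universe),
            "regulon_size_min": sizes[0] if sizes else 0,
            "regulon_size_max": sizes[-1] if sizes else 0,
            "regulon_sizes": sizes,
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_interactome(path, min_regulon_size: int = 20) -> Interactome:
    """Read the 4-column TSV dialect: regulator, target, mode (+1/-1), weight.

    Regulons below ``min_regulon_size`` are dropped (count logged);
    duplicate (regulator, target) rows and malformed mode/weight values are
    parse errors naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["regulator", "target", "mode", "weight"]
    if list(df.columns) != expected:
        raise InteractomeParseError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    pos: dict[str, dict[str, float]] = {}
    neg: dict[str, dict[str, float]] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        key = (row.regulator, row.target)
        if key in seen:
            raise InteractomeParseError(
                f"{path}, line {line}: duplicate edge {row.regulator} -> {row.target}"
            )
        seen.add(key)
        try:
            mode = int(row.mode)
        except (TypeError, ValueError):
            raise InteractomeParseError(
                f"{path}, line {line}: malformed mode {row.mode!r}"
            ) from None
        if mode not in (1, -1):
            raise InteractomeParseError(
                f"{path}, line {line}: mode must be +1 or -1, got {mode}"
            )
        try:
            weight = float(row.weight)
        except (TypeError, ValueError):
            raise InteractomeParseError(
                f"{path}, line {line}: malformed weight {row.weight!r}"
            ) from None
        bucket = pos if mode == 1 else neg
        bucket.setdefault(row.regulator, {})[row.target] = weight
    regulators = sorted(set(pos) | set(neg))
    universe = set(df["regulator"]) | set(df["target"])
    regulons = []
    n_dropped = 0
    for reg in regulators:
        r = Regulon(reg, pos.get(reg, {}), neg.get(reg, {}))
        if r.size < min_regulon_size:
            n_dropped += 1
            continue
        regulons.append(r)
    if n_dropped:
        logger.info(
            "read_interactome: dropped %d regulon(s) below %d targets",
            n_dropped, min_regulon_size,
        )
    return Interactome(regulons, universe)


def write_interactome(interactome: Interactome, path) -> None:
    """Write the 4-column TSV with deterministic row ordering."""
    rows = []
    for reg in interactome:
        regulon = interactome[reg]
        for tgt in sorted(regulon.positive):
            rows.append((reg, tgt, 1, regulon.positive[tgt]))
        for tgt in sorted(regulon.negative):
            rows.append((reg, tgt, -1, regulon.negative[tgt]))
    df = pd.DataFrame(rows, columns=["regulator", "target", "mode", "weight"])
    df.to_csv(path, sep="\t", index=False)


def restrict_to_signature(
    interactome: Interactome,
    sig: GeneSignature,
    min_regulon_size: int = 20,
) -> Interactome:
    """Drop targets absent from the signature; prune undersized regulons."""
    genes = sig.gene_set()
    kept = []
    n_dropped = 0
    for reg in interactome:
        regulon = interactome[reg]
        pos = {t: w for t, w in regulon.positive.items() if t in genes}
        neg = {t: w for t, w in regulon.negative.items() if t in genes}
        if len(pos) + len(neg) < min_regulon_size:
            n_dropped += 1
            continue
        kept.append(Regulon(reg, pos, neg))
    if n_dropped:
        logger.info(
            "restrict_to_signature: dropped %d regulon(s) below %d targets "
            "after restriction", n_dropped, min_regulon_size,
        )
    if not kept:
        raise ValueError("no regulon survives restriction to the signature")
    return Interactome(kept, interactome.universe | genes)


def translate_interactome(
    interactome: Interactome,
    omap: OrthologMap,
    min_regulon_size: int = 20,
) -> Interactome:
    """Translate regulator and target ids through an ortholog map.

    Regulators without an ortholog are dropped; a one-to-many regulator
    keeps its first (lexicographically smallest) ortholog.  Targets expand
    to all their orthologs with the same mode and weight.  Undersized
    translated regulons are pruned.
    """
    kept = []
    n_dropped = 0
    universe: set[str] = set()
    used: set[str] = set()
    for reg in interactome:
        if reg not in omap:
            n_dropped += 1
            continue
        new_reg = sorted(omap.targets(reg))[0]
        if new_reg in used:
            n_dropped += 1
            continue
        used.add(new_reg)
        regulon = interactome[reg]
        pos: dict[str, float] = {}
        neg: dict[str, float] = {}
        for src, w in regulon.positive.items():
            if src in omap:
                for dst in omap.targets(src):
                    if dst != new_reg:
                        pos[dst] = w
        for src, w in regulon.negative.items():
            if src in omap:
                for dst in omap.targets(src):
                    if dst != new_reg and dst not in pos:
                        neg[dst] = w
        if len(pos) + len(neg) < min_regulon_size:
            n_dropped += 1
            continue
        kept.append(Regulon(new_reg, pos, neg))
        universe |= {new_reg} | set(pos) | set(neg)
    if n_dropped:
        logger.info(
            "translate_interactome: dropped %d regulon(s) (no ortholog or "
            "undersized after translation)", n_dropped,
        )
    if not kept:
        raise ValueError("no regulon survives ortholog translation")
    return Interactome(kept, universe)
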