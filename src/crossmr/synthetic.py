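"""Synthetic study generator with planted ground truth.

Emulates the data shapes the pipeline consumes in the real study — a
regulon network per species, two-phenotype expression cohorts (e.g.,
pre-metastatic tumors versus metastases, >= 5 samples per group), a patient
cohort whose survival hazard depends on regulator activity, and a
mouse-to-human ortholog map with drop-outs and one-to-many entries — so
every downstream stage can be tested against a known truth.

The expression model is additive Gaussian on normalized values (the
pipeline consumes normalized expression by design; count-level simulation
is out of scope): group-2 samples, or patients in proportion to a latent
per-patient activity, shift each target of each planted regulator by
``mode * effect``.  All planted regulators share one latent activity per
patient, mimicking a coordinated multi-regulator program.

Everything derives from a single integer seed through fixed per-stage
sub-seeding, so any stage regenerates bit-identically in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regulons import Interactome, Regulon, translate_interactome
from .signatures import OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "StudyData",
    "stage_rng",
    "generate_interactome",
    "generate_two_group_cohort",
    "generate_survival_cohort",
    "generate_ortholog_map",
    "generate_study",
]

#: Fixed stage keys: every stage draws from its own child stream of the
#: global seed, so regenerating one stage never perturbs another.
_STAGE_KEYS = {
    "interactome": 0,
    "planted": 1,
    "two_group": 2,
    "survival": 3,
    "ortholog": 4,
}


def stage_rng(seed: int, stage: str, replicate: int = 0) -> np.random.Generator:
    """Deterministic per-stage random generator derived from the global seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage], int(replicate)))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the scale of the emulated study: 2000 genes, 100
    regulators with 20-60 targets each (70% positive mode), 8 planted
    regulators shifting their targets by one noise-SD per unit mode,
    8 samples per phenotype group, and a 200-patient survival cohort with
    log-hazard 0.8 per unit latent activity, exponential baseline rate
    0.02 events per time unit, administrative censoring at 120 time units,
    and an ortholog map losing 5% of genes and duplicating 2%.
    """

    n_genes: int = 2000
    n_regulators: int = 100
    regulon_size_range: tuple[int, int] = (20, 60)
    frac_positive_targets: float = 0.7
    n_planted: int = 8
    activity_effect: float = 1.0
    noise_sd: float = 1.0
    n_per_group: int = 8
    n_patients: int = 200
    hazard_beta: float = 0.8
    baseline_rate: float = 0.02
    censor_time: float = 120.0
    ortholog_drop_frac: float = 0.05
    ortholog_dup_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.regulon_size_range
        if not (0 < lo <= hi):
            raise ValueError("regulon_size_range must satisfy 0 < min <= max")
        if hi > self.n_genes:
            raise ValueError("max regulon size exceeds the gene universe")
        if self.n_planted > self.n_regulators:
            raise ValueError("n_planted exceeds n_regulators")
        for name in ("frac_positive_targets", "ortholog_drop_frac", "ortholog_dup_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_regulators > self.n_genes:
            raise ValueError("more regulators than genes")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regulon_size_range"] = list(self.regulon_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "regulon_size_range" in d:
            d["regulon_size_range"] = tuple(d["regulon_size_range"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded before any noise is drawn.

    ``latent_activity`` is populated only for survival cohorts (one shared
    latent activity per patient, scaled by each regulator's effect).
    """

    planted_regulators: tuple[str, ...]
    regulator_effects: dict = field(default_factory=dict)
    latent_activity: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_regulators": list(self.planted_regulators),
                    "regulator_effects": self.regulator_effects,
                    "latent_activity": self.latent_activity,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tuple(d["planted_regulators"]),
            d.get("regulator_effects", {}),
            d.get("latent_activity", {}),
        )


def _gene_universe(config: SyntheticConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def generate_interactome(config: SyntheticConfig) -> Interactome:
    """Random regulon network: each regulator gets 20-60 targets drawn from
    the gene universe (never itself), mode +1 with probability
    ``frac_positive_targets`` and -1 otherwise, weight 1."""
    rng = stage_rng(config.seed, "interactome")
    universe = _gene_universe(config)
    regulators = sorted(rng.choice(universe, size=config.n_regulators, replace=False))
    lo, hi = config.regulon_size_range
    regulons = []
    for reg in regulators:
        size = int(rng.integers(lo, hi + 1))
        candidates = [g for g in universe if g != reg]
        targets = rng.choice(candidates, size=size, replace=False)
        modes = rng.random(size) < config.frac_positive_targets
        pos = {t: 1.0 for t, m in zip(targets, modes) if m}
        neg = {t: 1.0 for t, m in zip(targets, modes) if not m}
        regulons.append(Regulon(reg, pos, neg))
    return Interactome(regulons, universe)


def _pick_planted(
    config: SyntheticConfig,
    interactome: Interactome,
    eligible: list[str] | None = None,
) -> PlantedTruth:
    rng = stage_rng(config.seed, "planted")
    pool = sorted(eligible if eligible is not None else list(interactome.regulons))
    if len(pool) < config.n_planted:
        raise ValueError(
            f"only {len(pool)} eligible regulators for {config.n_planted} planted"
        )
    planted = tuple(sorted(rng.choice(pool, size=config.n_planted, replace=False)))
    effects = {r: float(config.activity_effect) for r in planted}
    return PlantedTruth(planted, effects)


def _shift_vector(
    interactome: Interactome, truth: PlantedTruth, genes: list[str]
) -> np.ndarray:
    """Per-gene expression shift per unit activity: sum over planted
    regulators of mode * effect for each targeted gene."""
    index = {g: i for i, g in enumerate(genes)}
    shift = np.zeros(len(genes))
    for reg in truth.planted_regulators:
        effect = truth.regulator_effects[reg]
        regulon = interactome[reg]
        for tgt in regulon.positive:
            shift[index[tgt]] += effect
        for tgt in regulon.negative:
            shift[index[tgt]] -= effect
    return shift


def generate_two_group_cohort(
    config: SyntheticConfig,
    interactome: Interactome,
    truth: PlantedTruth | None = None,
    replicate: int = 0,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Two-phenotype expression cohort with planted regulator activity.

    Group A samples are pure baseline noise; group B samples add
    ``mode * effect`` to every target of every planted regulator (summed
    when a gene is targeted by several).  Pass ``truth`` to reuse a planted
    set across cohorts (e.g., mouse and human cohorts sharing one truth);
    ``replicate`` separates the noise streams of independent cohorts.
    """
    if truth is None:
        truth = _pick_planted(config, interactome)
    for reg in truth.planted_regulators:
        if reg not in interactome:
            raise ValueError(f"planted regulator {reg!r} not in interactome")
    rng = stage_rng(config.seed, "two_group", replicate)
    genes = sorted(interactome.universe)
    n = config.n_per_group
    X = rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * n))
    X[:, n:] += _shift_vector(interactome, truth, genes)[:, None]
    samples = [f"R{replicate}S{j:03d}" for j in range(2 * n)]
    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    labels = pd.Series(
        ["groupA"] * n + ["groupB"] * n, index=pd.Index(samples, name="sample"),
        name="group",
    )
    return matrix, labels, truth


def generate_survival_cohort(
    config: SyntheticConfig,
    interactome: Interactome,
    truth: PlantedTruth | None = None,
    replicate: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Patient cohort whose hazard follows planted regulator activity.

    Each patient carries one latent activity ``a ~ N(0, 1)`` shared by all
    planted regulators; expression adds ``mode * effect * a`` on planted
    targets, and the event time is exponential with rate
    ``baseline_rate * exp(hazard_beta * a)``, administratively censored at
    ``censor_time``.
    """
    if config.n_patients < 20:
        raise ValueError("survival cohorts need >= 20 patients to be stable")
    if truth is None:
        truth = _pick_planted(config, interactome)
    rng = stage_rng(config.seed, "survival", replicate)
    genes = sorted(interactome.universe)
    n = config.n_patients
    activity = rng.normal(0.0, 1.0, size=n)
    X = rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    X += np.outer(_shift_vector(interactome, truth, genes), activity)
    rate = config.baseline_rate * np.exp(config.hazard_beta * activity)
    # one standard-exponential draw per patient, rescaled by the patient rate
    raw_times = np.where(
        rate > 0, rng.standard_exponential(n) / np.where(rate > 0, rate, 1.0), np.inf
    )
    event = (raw_times < config.censor_time).astype(int)
    time = np.minimum(raw_times, config.censor_time)
    patients = [f"P{j:04d}" for j in range(n)]
    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=patients)
    clinical = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(patients, name="sample")
    )
    truth = PlantedTruth(
        truth.planted_regulators,
        dict(truth.regulator_effects),
        {p: float(a) for p, a in zip(patients, activity)},
    )
    if event.sum() == 0:
        logger.warning("generate_survival_cohort: cohort has zero events")
    return matrix, clinical, truth


def generate_ortholog_map(config: SyntheticConfig, genes: list[str]) -> OrthologMap:
    """Mouse -> human gene map with drop-outs and one-to-many entries.

    Every surviving source gene gets a distinct target id; a fixed fraction
    of source genes (rounded count) is omitted, and another fraction maps
    to two target ids.
    """
    if not genes:
        raise ValueError("empty gene universe")
    rng = stage_rng(config.seed, "ortholog")
    genes = sorted(genes)
    n = len(genes)
    n_drop = int(round(config.ortholog_drop_frac * n))
    n_dup = int(round(config.ortholog_dup_frac * n))
    dropped = set(rng.choice(genes, size=n_drop, replace=False)) if n_drop else set()
    kept = [g for g in genes if g not in dropped]
    n_dup = min(n_dup, len(kept))
    duplicated = set(rng.choice(kept, size=n_dup, replace=False)) if n_dup else set()
    mapping: dict[str, tuple[str, ...]] = {}
    extra = n
    for i, g in enumerate(kept):
        targets = (f"H{i:05d}",)
        if g in duplicated:
            targets = targets + (f"H{extra:05d}",)
            extra += 1
        mapping[g] = targets
    return OrthologMap(mapping)


@dataclass(frozen=True)
class StudyData:
    """One complete synthetic cross-species study."""

    config: SyntheticConfig
    mouse_interactome: Interactome
    human_interactome: Interactome
    ortholog_map: OrthologMap
    mouse_expression: pd.DataFrame
    mouse_labels: pd.Series
    human_expression: pd.DataFrame
    human_labels: pd.Series
    survival_expression: pd.DataFrame
    clinical: pd.DataFrame
    mouse_truth: PlantedTruth
    human_truth: PlantedTruth


def generate_study(config: SyntheticConfig) -> StudyData:
    """Generate a matched mouse cohort, human cohort and human survival
    cohort sharing one planted truth across species.

    The human interactome is the mouse network translated through the
    ortholog map, and planted regulators are drawn from regulators whose
    regulons survive translation — a cross-species study is only defined
    for regulators comparable in both species.
    """
    inter_m = generate_interactome(config)
    omap = generate_ortholog_map(config, sorted(inter_m.universe))
    min_size = max(2, config.regulon_size_range[0] // 2)
    inter_h = translate_interactome(inter_m, omap, min_regulon_size=min_size)
    eligible = [
        r for r in inter_m.regulons
        if r in omap and sorted(omap.targets(r))[0] in inter_h
    ]
    truth_m = _pick_planted(config, inter_m, eligible)
    truth_h = PlantedTruth(
        tuple(sorted(sorted(omap.targets(r))[0] for r in truth_m.planted_regulators)),
        {
            sorted(omap.targets(r))[0]: e
            for r, e in truth_m.regulator_effects.items()
        },
    )
    expr_m, labels_m, _ = generate_two_group_cohort(config, inter_m, truth_m, replicate=0)
    expr_h, labels_h, _ = generate_two_group_cohort(config, inter_h, truth_h, replicate=1)
    expr_s, clinical, truth_h_full = generate_survival_cohort(config, inter_h, truth_h)
    return StudyData(
        config, inter_m, inter_h, omap,
        expr_m, labels_m, expr_h, labels_h, expr_s, clinical,
        truth_m, truth_h_full,
    )
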