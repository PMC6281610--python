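"""Configuration-driven orchestration of the full discovery pipeline.

Stages (in order): ``simulate`` (synthetic study generation), ``signature``
(Welch-t signatures, humanization, exploratory PCA), ``gsea``
(cross-species two-tail GSEA QC with leading-edge overlap), ``marina``
(per-species regulon activity), ``integrate`` (Stouffer integration and
conserved-MR filtering), ``activity`` (per-patient activity matrix),
``survival`` (Cox screen, k-means stratification, Kaplan-Meier/log-rank)
and ``null`` (random-MR-set empirical specificity).

Every stage reads its inputs from and writes its outputs to the run
directory as plain TSV/JSON, appends its parameters and derived seeds to
``manifest.json``, and is individually re-runnable; reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .enrichment import leading_edge_overlap_test, pathway_enrichment, two_tail_gsea
from .mr import (
    annotation_filter,
    filter_conserved,
    marina_activity,
    sample_activity_matrix,
    stouffer_integrate,
)
from .regulons import read_interactome, write_interactome
from .signatures import humanize_signature, welch_t_signature
from .surv import cox_screen, km_logrank, kmeans_stratify, random_set_null
from .synthetic import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "STAGES", "run_pipeline", "compute_pca"]

STAGES = (
    "simulate", "signature", "gsea", "marina",
    "integrate", "activity", "survival", "null",
)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs from earlier stages are retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated parameters for one pipeline run."""

    seed: int = 0
    outdir: str = "results"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    top_n: int = 200
    n_perm: int = 1000
    sample_n_perm: int = 100
    weight_exponent: float = 1.0
    mr_weight_exponent: float = 0.0
    min_regulon_size: int = 20
    stouffer_p: float = 1e-4
    require_concordance: bool = True
    direction: str = "activated"
    cox_p: float = 0.05
    n_candidates: int = 8
    kmeans_restarts: int = 100
    null_iterations: int = 1000
    null_kmeans_restarts: int = 10
    annotation_file: str | None = None
    gmt_file: str | None = None
    stages: tuple = STAGES

    def __post_init__(self):
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig.from_dict(self.synthetic)
        # the pipeline seed is the single global seed
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        for name in ("top_n", "n_perm", "sample_n_perm", "n_candidates",
                     "kmeans_restarts", "null_iterations", "null_kmeans_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.stouffer_p < 1) or not (0 < self.cox_p < 1):
            raise ValueError("p thresholds must lie in (0, 1)")
        if self.direction not in ("activated", "repressed", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage integer seed below 2**31."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=int(self.seed), spawn_key=(1000, idx))
        return int(ss.generate_state(1)[0] % (2**31))


def compute_pca(
    matrix: pd.DataFrame, groups: pd.Series | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Exploratory PCA of samples in gene space.

    Centered SVD; each component is flipped so its largest-|loading| gene
    loads positively (a fixed sign convention for cross-platform
    determinism).  Returns (scores table, variance-explained fractions).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = matrix.to_numpy(float).T
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        U * S,
        index=pd.Index(matrix.columns, name="sample"),
        columns=[f"PC{i + 1}" for i in range(S.size)],
    )
    if groups is not None:
        scores.insert(0, "group", groups.reindex(scores.index))
    return scores, frac


def _update_manifest(outdir: Path, stage: str, entry: dict) -> None:
    path = outdir / "manifest.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest[stage] = entry
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    study = generate_study(config.synthetic)
    io.write_expression(study.mouse_expression, outdir / "mouse_expression.tsv")
    io.write_labels(study.mouse_labels, outdir / "mouse_labels.tsv")
    io.write_expression(study.human_expression, outdir / "human_expression.tsv")
    io.write_labels(study.human_labels, outdir / "human_labels.tsv")
    io.write_expression(study.survival_expression, outdir / "survival_expression.tsv")
    io.write_clinical(study.clinical, outdir / "clinical.tsv")
    write_interactome(study.mouse_interactome, outdir / "mouse_interactome.tsv")
    write_interactome(study.human_interactome, outdir / "human_interactome.tsv")
    io.write_ortholog_map(study.ortholog_map, outdir / "ortholog_map.tsv")
    study.mouse_truth.to_json(outdir / "truth_mouse.json")
    study.human_truth.to_json(outdir / "truth_human.json")
    _update_manifest(outdir, "simulate", {
        "seed": config.seed,
        "synthetic": config.synthetic.to_dict(),
        "n_mouse_regulons": len(study.mouse_interactome),
        "n_human_regulons": len(study.human_interactome),
        "planted": list(study.mouse_truth.planted_regulators),
    })


def _stage_signature(config: PipelineConfig, outdir: Path) -> None:
    dropped = {}
    for species in ("mouse", "human"):
        matrix = io.read_expression(outdir / f"{species}_expression.tsv")
        labels = io.read_labels(outdir / f"{species}_labels.tsv")
        sig = welch_t_signature(matrix, labels, "groupA", "groupB")
        io.write_signature(sig, outdir / f"signature_{species}.tsv")
        dropped[species] = matrix.shape[0] - len(sig)
    omap = io.read_ortholog_map(outdir / "ortholog_map.tsv")
    mouse_sig = io.read_signature(outdir / "signature_mouse.tsv")
    humanized = humanize_signature(mouse_sig, omap)
    io.write_signature(humanized, outdir / "signature_mouse_humanized.tsv")
    matrix = io.read_expression(outdir / "mouse_expression.tsv")
    labels = io.read_labels(outdir / "mouse_labels.tsv")
    scores, frac = compute_pca(matrix, labels)
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(frac.size)], "variance_fraction": frac}
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
    _update_manifest(outdir, "signature", {
        "test": "welch_t", "genes_dropped": dropped,
        "pc1_variance_fraction": float(frac[0]),
    })


def _stage_gsea(config: PipelineConfig, outdir: Path) -> None:
    seed = config.stage_seed("gsea")
    human = io.read_signature(outdir / "signature_human.tsv")
    humanized = io.read_signature(outdir / "signature_mouse_humanized.tsv")
    fwd_pos, fwd_neg = two_tail_gsea(
        human, humanized, config.top_n, config.n_perm, seed, config.weight_exponent
    )
    rev_pos, rev_neg = two_tail_gsea(
        humanized, human, config.top_n, config.n_perm, seed + 1, config.weight_exponent
    )
    rows = []
    for name, r in (
        ("mouse_in_human_positive", fwd_pos), ("mouse_in_human_negative", fwd_neg),
        ("human_in_mouse_positive", rev_pos), ("human_in_mouse_negative", rev_neg),
    ):
        rows.append({
            "comparison": name, "es": r.es, "nes": r.nes, "p": r.p,
            "n_leading": len(r.leading_edge),
            "leading_edge": ",".join(sorted(r.leading_edge)),
        })
    pd.DataFrame(rows).to_csv(outdir / "gsea_two_tail.tsv", sep="\t", index=False)
    universe = sorted(human.gene_set() & humanized.gene_set())
    overlaps = []
    for tail, a, b in (
        ("positive", fwd_pos.leading_edge, rev_pos.leading_edge),
        ("negative", fwd_neg.leading_edge, rev_neg.leading_edge),
    ):
        frac, chi2, p = leading_edge_overlap_test(a, b, universe)
        overlaps.append({
            "tail": tail, "overlap_fraction": frac, "chi_square": chi2, "p": p,
        })
    pd.DataFrame(overlaps).to_csv(outdir / "gsea_overlap.tsv", sep="\t", index=False)
    entry = {"seed": seed, "top_n": config.top_n, "n_perm": config.n_perm}
    if config.gmt_file:
        sets = io.read_gmt(config.gmt_file)
        table = pathway_enrichment(
            humanized, sets, config.n_perm, seed + 2, config.weight_exponent
        )
        table.to_csv(outdir / "pathway_enrichment.tsv", sep="\t")
        entry["n_gene_sets"] = len(sets)
    _update_manifest(outdir, "gsea", entry)


def _stage_marina(config: PipelineConfig, outdir: Path) -> None:
    seed = config.stage_seed("marina")
    for i, (species, signame) in enumerate(
        (("mouse", "signature_mouse"), ("human", "signature_human"))
    ):
        sig = io.read_signature(outdir / f"{signame}.tsv")
        inter = read_interactome(
            outdir / f"{species}_interactome.tsv", config.min_regulon_size
        )
        table = marina_activity(
            inter, sig, config.n_perm, seed + i, config.mr_weight_exponent,
            min_regulon_size=config.min_regulon_size,
        )
        table.to_csv(outdir / f"marina_{species}.tsv", sep="\t")
    _update_manifest(outdir, "marina", {
        "seed": seed, "n_perm": config.n_perm,
        "min_regulon_size": config.min_regulon_size,
    })


def _stage_integrate(config: PipelineConfig, outdir: Path) -> None:
    mouse = pd.read_csv(outdir / "marina_mouse.tsv", sep="\t", index_col="regulator")
    human = pd.read_csv(outdir / "marina_human.tsv", sep="\t", index_col="regulator")
    omap = io.read_ortholog_map(outdir / "ortholog_map.tsv")
    table = stouffer_integrate(mouse, human, omap)
    table.to_csv(outdir / "conserved_mr.tsv", sep="\t")
    filtered = filter_conserved(
        table, config.stouffer_p, config.require_concordance, config.direction
    )
    filtered.to_csv(outdir / "conserved_filtered.tsv", sep="\t")
    entry = {
        "n_integrated": int(len(table)), "n_filtered": int(len(filtered)),
        "p_threshold": config.stouffer_p,
        "require_concordance": config.require_concordance,
        "direction": config.direction,
    }
    if config.annotation_file:
        with open(config.annotation_file) as fh:
            annotation = {line.strip() for line in fh if line.strip()}
        annotated = annotation_filter(filtered, annotation)
        annotated.to_csv(outdir / "conserved_annotated.tsv", sep="\t")
        entry["n_annotated"] = int(len(annotated))
    _update_manifest(outdir, "integrate", entry)


def _stage_activity(config: PipelineConfig, outdir: Path) -> None:
    seed = config.stage_seed("activity")
    inter = read_interactome(
        outdir / "human_interactome.tsv", config.min_regulon_size
    )
    matrix = io.read_expression(outdir / "survival_expression.tsv")
    activity = sample_activity_matrix(
        inter, matrix, config.sample_n_perm, seed, config.mr_weight_exponent,
        min_regulon_size=config.min_regulon_size,
    )
    activity.to_csv(outdir / "activity_matrix.tsv", sep="\t")
    _update_manifest(outdir, "activity", {
        "seed": seed, "n_perm": config.sample_n_perm,
        "n_regulators": int(activity.shape[0]), "n_samples": int(activity.shape[1]),
    })


def _stage_survival(config: PipelineConfig, outdir: Path) -> None:
    seed = config.stage_seed("survival")
    activity = pd.read_csv(outdir / "activity_matrix.tsv", sep="\t", index_col="regulator")
    clinical = io.read_clinical(outdir / "clinical.tsv")
    screen = cox_screen(activity, clinical)
    screen.to_csv(outdir / "cox_screen.tsv", sep="\t")
    significant = screen[
        screen["converged"] & (screen["p"] < config.cox_p) & (screen["log_hr"] > 0)
    ].sort_values("p")
    filtered_path = outdir / "conserved_filtered.tsv"
    candidates = list(significant.index)
    if filtered_path.exists():
        conserved = pd.read_csv(filtered_path, sep="\t", index_col="regulator")
        in_conserved = [r for r in candidates if r in conserved.index]
        if in_conserved:
            candidates = in_conserved
        else:
            logger.warning(
                "survival: no Cox-significant regulator in the conserved set; "
                "falling back to the Cox screen alone"
            )
    candidates = candidates[: config.n_candidates]
    if not candidates:
        raise ValueError("no candidate regulator passes the Cox screen")
    (outdir / "candidates.txt").write_text("\n".join(candidates) + "\n")
    labels = kmeans_stratify(activity.loc[candidates], config.kmeans_restarts, seed)
    io.write_labels(labels, outdir / "stratification_labels.tsv")
    result = km_logrank(labels, clinical)
    result.km_curves.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    summary = {
        "candidates": candidates,
        "n_high": int((labels == "high").sum()),
        "n_low": int((labels == "low").sum()),
        "logrank_stat": result.logrank_stat,
        "logrank_p": result.logrank_p,
        "hazard_ratio": result.hazard_ratio,
        "hr_ci_low": result.hr_ci[0],
        "hr_ci_high": result.hr_ci[1],
    }
    (outdir / "survival_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    _update_manifest(outdir, "survival", {
        "seed": seed, "cox_p": config.cox_p,
        "n_significant": int(len(significant)), "candidates": candidates,
        "kmeans_restarts": config.kmeans_restarts,
    })


def _stage_null(config: PipelineConfig, outdir: Path) -> None:
    seed = config.stage_seed("null")
    activity = pd.read_csv(outdir / "activity_matrix.tsv", sep="\t", index_col="regulator")
    clinical = io.read_clinical(outdir / "clinical.tsv")
    summary = json.loads((outdir / "survival_summary.json").read_text())
    candidates = summary["candidates"]
    null = random_set_null(
        activity, clinical, summary["logrank_p"],
        target_set_size=min(config.n_candidates, len(candidates)),
        n_iter=config.null_iterations, seed=seed,
        n_restarts=config.null_kmeans_restarts,
        exclude=candidates,
    )
    null.to_json(outdir / "null_model.json")
    _update_manifest(outdir, "null", {
        "seed": seed, "n_iter": config.null_iterations,
        "pool": "all tested regulators minus the candidate set",
        "pool_size": int(activity.shape[0]) - len(candidates),
        "empirical_p": null.empirical_p,
        "n_degenerate": null.n_degenerate,
    })


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "signature": _stage_signature,
    "gsea": _stage_gsea,
    "marina": _stage_marina,
    "integrate": _stage_integrate,
    "activity": _stage_activity,
    "survival": _stage_survival,
    "null": _stage_null,
}


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the enabled stages in order; returns the run directory.

    A stage failure aborts with :class:`PipelineStageError` naming the
    stage; outputs of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    selected = tuple(stages) if stages is not None else config.stages
    for stage in STAGES:
        if stage not in selected:
            continue
        logger.info("pipeline: running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(stage, exc) from exc
    return outdir
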