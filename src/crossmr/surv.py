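"""Clinical prioritization of master regulators.

Four stages: (1) a univariate Cox proportional-hazards screen of every
regulator's continuous activity against survival, with Wald significance;
(2) two-group k-means stratification of patients in candidate-MR activity
space ("high" = the cluster with larger mean activity); (3) Kaplan-Meier /
log-rank comparison of the two groups with a hazard ratio from a
proportional-hazards fit on the group indicator; and (4) an empirical
specificity null that repeats the stratification for many random
equally-sized regulator sets and asks how often a random set reaches or
outperforms the observed log-rank p ("reached or outperformed" is
inclusive, <=).  The empirical p uses the add-one correction
``(1 + #{null <= observed}) / (n_iter + 1)`` so it is never reported as 0.

Model fitting stands on lifelines; time units are opaque and pass through
unchanged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "NoEventsError",
    "DegenerateClusteringError",
    "StratificationResult",
    "EmpiricalNull",
    "cox_screen",
    "kmeans_stratify",
    "km_logrank",
    "random_set_null",
]


class NoEventsError(ValueError):
    """Survival analysis requested on a cohort with zero observed events."""


class DegenerateClusteringError(ValueError):
    """All patients identical in activity space; no two-group split exists."""


def _align(activity: pd.DataFrame, clinical: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    common = activity.columns.intersection(clinical.index)
    return activity[common], clinical.loc[common]


def cox_screen(activity: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox fit per regulator: continuous activity vs survival.

    Requires >= 20 matched samples with >= 5 events.  Constant activity
    rows and non-converged fits are flagged (``converged = False``), never
    silently dropped.  Returns a table with ``log_hr``, ``wald_z``, ``p``
    and ``converged`` per regulator.
    """
    act, clin = _align(activity, clinical)
    if act.shape[1] < 20:
        raise ValueError(f"only {act.shape[1]} matched samples; need >= 20")
    n_events = int(clin["event"].sum())
    if n_events == 0:
        raise NoEventsError("cohort has zero events")
    if n_events < 5:
        raise ValueError(f"only {n_events} events; need >= 5")
    rows = []
    for reg in act.index:
        x = act.loc[reg].to_numpy(float)
        if np.ptp(x) == 0:
            logger.warning("cox_screen: constant activity for %s; flagged", reg)
            rows.append(
                {"regulator": reg, "log_hr": np.nan, "wald_z": np.nan,
                 "p": np.nan, "converged": False}
            )
            continue
        df = pd.DataFrame(
            {"time": clin["time"].to_numpy(float), "event": clin["event"].to_numpy(int),
             "activity": x}
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["activity"]
            rows.append(
                {"regulator": reg, "log_hr": float(s["coef"]),
                 "wald_z": float(s["z"]), "p": float(s["p"]), "converged": True}
            )
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            logger.warning("cox_screen: fit failed for %s; flagged", reg)
            rows.append(
                {"regulator": reg, "log_hr": np.nan, "wald_z": np.nan,
                 "p": np.nan, "converged": False}
            )
    return pd.DataFrame(rows).set_index("regulator")


def kmeans_stratify(
    activity: pd.DataFrame,
    n_restarts: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Two-group k-means over patients in MR-activity space.

    Euclidean k-means (best of ``n_restarts`` by within-cluster sum of
    squares); the cluster with the larger mean activity, averaged over
    regulators and its patients, is labeled ``high``.
    """
    if activity.shape[1] < 2:
        raise ValueError("need at least 2 samples to stratify")
    if activity.shape[0] < 1:
        raise ValueError("need at least one regulator row")
    X = activity.T.to_numpy(float)
    if np.allclose(X, X[0]):
        raise DegenerateClusteringError("all patients identical in activity space")
    km = KMeans(
        n_clusters=2, n_init=int(n_restarts), random_state=int(seed) % (2**31),
    ).fit(X)
    assign = km.labels_
    means = [X[assign == c].mean() for c in (0, 1)]
    high_cluster = int(np.argmax(means))
    labels = np.where(assign == high_cluster, "high", "low")
    return pd.Series(labels, index=activity.columns, name="group")


@dataclass(frozen=True)
class StratificationResult:
    """Two-group survival comparison."""

    labels: pd.Series
    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    km_curves: pd.DataFrame | None = None


def km_logrank(
    labels: pd.Series,
    clinical: pd.DataFrame,
    compute_hr: bool = True,
    compute_curves: bool = True,
) -> StratificationResult:
    """Log-rank test and hazard ratio for a high/low patient partition.

    The hazard ratio (high vs low, with 95% CI) comes from a Cox fit on
    the group indicator; Kaplan-Meier curve coordinates are attached for
    export unless disabled.
    """
    common = labels.index.intersection(clinical.index)
    labels = labels.loc[common]
    clin = clinical.loc[common]
    hi = labels == "high"
    lo = labels == "low"
    if not hi.any() or not lo.any():
        raise ValueError("both groups must be nonempty")
    if int(clin["event"].sum()) == 0:
        raise NoEventsError("no events in the cohort")
    t_hi, e_hi = clin.loc[hi, "time"], clin.loc[hi, "event"]
    t_lo, e_lo = clin.loc[lo, "time"], clin.loc[lo, "event"]
    res = logrank_test(t_hi, t_lo, event_observed_A=e_hi, event_observed_B=e_lo)
    hr, ci = np.nan, (np.nan, np.nan)
    if compute_hr:
        df = pd.DataFrame(
            {"time": clin["time"].to_numpy(float),
             "event": clin["event"].to_numpy(int),
             "high": hi.to_numpy(int)}
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["high"]
            with np.errstate(over="ignore"):
                hr = float(np.exp(s["coef"]))
                ci = (
                    float(np.exp(s["coef lower 95%"])),
                    float(np.exp(s["coef upper 95%"])),
                )
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            logger.warning("km_logrank: hazard-ratio fit failed; reporting NaN")
    curves = None
    if compute_curves:
        parts = []
        for name, t, e in (("high", t_hi, e_hi), ("low", t_lo, e_lo)):
            kmf = KaplanMeierFitter()
            kmf.fit(t, e, label=name)
            sf = kmf.survival_function_.reset_index()
            sf.columns = ["time", "survival"]
            sf.insert(0, "group", name)
            parts.append(sf)
        curves = pd.concat(parts, ignore_index=True)
    return StratificationResult(
        labels, float(res.test_statistic), float(res.p_value), hr, ci, curves
    )


@dataclass(frozen=True)
class EmpiricalNull:
    """Random-MR-set specificity null for an observed log-rank p."""

    observed_p: float
    null_p: np.ndarray
    empirical_p: float
    n_degenerate: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "observed_p": self.observed_p,
                    "empirical_p": self.empirical_p,
                    "n_iter": int(self.null_p.size),
                    "n_degenerate": self.n_degenerate,
                    "null_p": [float(p) for p in self.null_p],
                },
                fh, indent=2,
            )
            fh.write("\n")


def random_set_null(
    activity: pd.DataFrame,
    clinical: pd.DataFrame,
    observed_p: float,
    target_set_size: int = 8,
    n_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 10,
    exclude=(),
) -> EmpiricalNull:
    """Empirical specificity of a candidate-MR stratification.

    Each iteration samples ``target_set_size`` regulators uniformly without
    replacement from the pool (the rows of ``activity``, minus any
    regulators in ``exclude``), stratifies patients by k-means on their
    activity, and records the log-rank p.  Pass the candidate set itself as
    ``exclude`` to ask whether the candidates outperform random sets of
    *other* regulators; the default (empty) draws from the full pool.
    Iterations that degenerate (no split, no events) count as p = 1,
    conservatively.  The empirical p is the add-one-corrected fraction of
    null p-values at or below the observed one.
    """
    excluded = frozenset(exclude)
    pool = [r for r in activity.index if r not in excluded]
    if len(pool) <= target_set_size:
        raise ValueError(
            f"pool of {len(pool)} regulators cannot host random sets of "
            f"{target_set_size}"
        )
    rng = np.random.default_rng(seed)
    null_p = np.ones(n_iter)
    n_degenerate = 0
    for i in range(n_iter):
        regs = rng.choice(pool, size=target_set_size, replace=False)
        kseed = int(rng.integers(2**31))
        try:
            labels = kmeans_stratify(activity.loc[regs], n_restarts, kseed)
            r = km_logrank(labels, clinical, compute_hr=False, compute_curves=False)
            null_p[i] = r.logrank_p
        except (DegenerateClusteringError, NoEventsError, ValueError):
            n_degenerate += 1
            null_p[i] = 1.0
    if n_degenerate:
        logger.warning(
            "random_set_null: %d/%d degenerate iteration(s) scored p = 1",
            n_degenerate, n_iter,
        )
    emp = (1 + int(np.count_nonzero(null_p <= observed_p))) / (n_iter + 1)
    return EmpiricalNull(float(observed_p), null_p, float(emp), n_degenerate)
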