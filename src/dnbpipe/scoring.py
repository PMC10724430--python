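"""Per-patient DNB score trajectories, the 2h-4h difference, clinical
correlation and remission/flare prediction.

Once a cohort-wide core set is fixed, each patient's DNB score at each
stimulation timepoint is the composite index of that core; the prognostic
parameter is delta = score(2h) - score(4h). Higher delta tracks lower
disease activity (the score surge at 2 h that recedes by 4 h marks a
responsive immune network), so delta >= threshold predicts a
remission-like trajectory and delta < threshold a flare-like one.
"""
from __future__ import annotations

from itertools import permutations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import EPSILON, PanelSummary
from .errors import MissingTimepointError
from .types import (
    TIMEPOINTS,
    ClinicalRecord,
    CoreSet,
    ScoreTrajectory,
    TimeCourseSample,
)

MIN_PAIRS = 5
EXACT_PERMUTATION_MAX_N = 9


def score_trajectory(
    sample: TimeCourseSample,
    core: CoreSet | Sequence[str],
    threshold: float = 0.0,
    indeterminate_band: float = 0.0,
    epsilon: float = EPSILON,
) -> ScoreTrajectory:
    """DNB score of ``sample`` at every timepoint on a fixed core set.

    The core is fixed cohort-wide: no per-sample re-ranking happens here.
    """
    markers = tuple(core.markers if isinstance(core, CoreSet) else core)
    if len(markers) < 2:
        raise ValueError("core must contain at least 2 markers")
    missing = [m for m in markers if m not in sample.marker_names]
    if missing:
        raise KeyError(
            f"core markers {missing} absent from panel of {sample.patient_id}"
        )
    score = {}
    for t, matrix in sample.matrices.items():
        summary = PanelSummary.from_matrix(matrix)
        score[t] = summary.module_stats(markers, epsilon=epsilon).index
    traj = ScoreTrajectory(
        patient_id=sample.patient_id, score=score,
        delta=score[2.0] - score[4.0],
    )
    traj.prediction = predict_outcome(traj, threshold=threshold,
                                      indeterminate_band=indeterminate_band)
    traj.threshold_used = threshold
    return traj


def delta_score(traj: ScoreTrajectory, t_a: float = 2.0,
                t_b: float = 4.0) -> float:
    """score(t_a) - score(t_b); antisymmetric in its arguments."""
    for t in (t_a, t_b):
        if t not in traj.score:
            raise MissingTimepointError(
                f"trajectory {traj.patient_id}: no score at {t} h"
            )
    return traj.score[t_a] - traj.score[t_b]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n).

    With the x-ranks fixed, rho is a linear function of S = sum rx*ry[perm],
    so the full n! null can be evaluated vectorized on S alone (midranks
    handled automatically since ranks are permuted, not recomputed).
    """
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    n = len(x)
    perms = np.array(list(permutations(range(n))), dtype=np.int8)
    s_null = ry[perms] @ rx                     # n! values of S
    centre = n * rx.mean() * ry.mean()
    scale = n * rx.std(ddof=0) * ry.std(ddof=0)
    rho_null = (s_null - centre) / scale
    return float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))


def clinical_correlation(
    deltas: Mapping[str, float],
    clinical: Sequence[ClinicalRecord],
    variable: str = "SLEDAI",
) -> tuple[float, float]:
    """Spearman rank correlation between per-patient delta and a clinical
    variable (SLEDAI or ESR), midrank ties, two-sided p.

    Uses the exact permutation null for n <= 9 paired observations (cohort
    sizes here sit at that boundary) and the large-sample approximation
    otherwise.
    """
    attr = {"SLEDAI": "sledai", "ESR": "esr"}.get(variable)
    if attr is None:
        raise ValueError(f"unknown clinical variable {variable!r}")
    pairs = [
        (deltas[rec.patient_id], getattr(rec, attr))
        for rec in clinical
        if rec.patient_id in deltas and getattr(rec, attr) is not None
    ]
    if len(pairs) < MIN_PAIRS:
        raise ValueError(
            f"only {len(pairs)} paired observations; need >= {MIN_PAIRS}"
        )
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant variable: Spearman correlation undefined")
    rho = float(sstats.spearmanr(x, y).statistic)
    if len(x) <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(sstats.spearmanr(x, y).pvalue)
    return rho, p


def predict_outcome(traj: ScoreTrajectory, threshold: float = 0.0,
                    indeterminate_band: float = 0.0) -> str:
    """Trajectory-level prediction from delta against a threshold.

    delta >= threshold -> "remission" trajectory, delta < threshold ->
    "flare"; within +/- indeterminate_band of the threshold ->
    "indeterminate". Exactly at the threshold with zero band counts as
    remission (>= convention).
    """
    d = traj.delta
    if indeterminate_band > 0 and abs(d - threshold) < indeterminate_band:
        return "indeterminate"
    return "remission" if d >= threshold else "flare"


def cohort_report(
    trajectories: Sequence[ScoreTrajectory],
    clinical: Sequence[ClinicalRecord],
) -> dict:
    """Cohort summary: per-group mean trajectory, per-patient deltas with
    outcomes, clinical correlation table. Deterministically ordered."""
    if not trajectories:
        raise ValueError("no trajectories")
    by_id = {rec.patient_id: rec for rec in clinical}
    rows = []
    for traj in sorted(trajectories, key=lambda t: t.patient_id):
        rec = by_id.get(traj.patient_id)
        rows.append({
            "patient_id": traj.patient_id,
            "group": rec.group if rec else "unknown",
            **{f"score_{t:g}h": traj.score[t] for t in TIMEPOINTS},
            "delta": traj.delta,
            "prediction": traj.prediction,
            "outcome": rec.outcome if rec else "unknown",
        })
    patients = pd.DataFrame(rows)

    group_mean = (
        patients
        .groupby("group", sort=True)[[f"score_{t:g}h" for t in TIMEPOINTS]]
        .mean()
    )

    deltas = {r["patient_id"]: r["delta"] for r in rows}
    correlations = {}
    for variable in ("SLEDAI", "ESR"):
        try:
            rho, p = clinical_correlation(deltas, clinical, variable)
            correlations[variable] = {"rho": rho, "p": p}
        except ValueError:
            correlations[variable] = None

    known = patients[patients["outcome"].isin(["remission", "flare"])]
    accuracy = (
        float((known["prediction"] == known["outcome"]).mean())
        if len(known) else None
    )
    return {
        "patients": patients,
        "group_mean_trajectory": group_mean,
        "correlations": correlations,
        "prediction_accuracy": accuracy,
        "n_predicted": int(len(known)),
    }


def truth_optimal_threshold(deltas: Sequence[float],
                            outcomes: Sequence[str]) -> float:
    """Threshold on delta maximizing agreement with known outcomes.

    Candidate thresholds are midpoints between consecutive sorted deltas
    (plus the extremes); ties resolved toward the smallest threshold.
    Used when no externally fixed cutoff is available.
    """
    d = np.asarray(deltas, dtype=float)
    y = np.asarray([1 if o == "remission" else 0 for o in outcomes])
    if len(d) != len(y) or len(d) == 0:
        raise ValueError("deltas and outcomes must be equal-length, nonempty")
    order = np.sort(d)
    candidates = np.concatenate(
        [[order[0] - 1.0], (order[:-1] + order[1:]) / 2.0, [order[-1] + 1.0]]
    )
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = float(((d >= t).astype(int) == y).mean())
        if acc > best_acc + 1e-12:
            best_t, best_acc = float(t), acc
    return best_t
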