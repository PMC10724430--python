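"""Core in-memory containers for stimulation time-course cytometry data.

The unit of measurement is one blood draw: a cells x markers intensity
matrix for one (patient, timepoint). A patient's sample is the ordered map
timepoint -> matrix over the five IL-2 stimulation hours {0, 0.5, 1, 2, 4}.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import MissingTimepointError

#: IL-2 stimulation timepoints in hours: unstimulated baseline plus four
#: post-stimulation draws.
TIMEPOINTS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)

#: Cohort groups: healthy controls, active SLE (SLEDAI > 5), remission SLE
#: (SLEDAI <= 5).
GROUPS: tuple[str, ...] = ("HC", "aSLE", "rSLE")

RAW = "raw"


def arcsinh_state(cofactor: float) -> str:
    return f"arcsinh({cofactor:g})"


@dataclass
class ExpressionMatrix:
    """Cells x markers intensity table for one (patient, timepoint).

    Parameters
    ----------
    values
        Float array of shape (n_cells, n_markers). Raw ion intensities or
        arcsinh-transformed values depending on ``transform_state``.
    marker_names
        Unique, ordered marker (antibody) names, one per column.
    transform_state
        ``"raw"`` or ``"arcsinh(<cofactor>)"``.
    cluster_labels
        Optional per-cell category (e.g. gated cell population), length
        n_cells.
    """

    values: np.ndarray
    marker_names: tuple[str, ...]
    transform_state: str = RAW
    cluster_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.marker_names = tuple(self.marker_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x markers)")
        if self.values.shape[1] != len(self.marker_names):
            raise ValueError(
                f"{self.values.shape[1]} columns vs "
                f"{len(self.marker_names)} marker names"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if self.values.shape[0] < 1:
            raise ValueError("matrix must contain at least one cell")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing values after ingest")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
            if len(self.cluster_labels) != self.n_cells:
                raise ValueError("cluster_labels length != number of cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices of ``names``, raising KeyError on unknown markers."""
        pos = {m: i for i, m in enumerate(self.marker_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"markers not in panel: {missing}")
        return np.array([pos[n] for n in names], dtype=int)

    def with_values(self, values: np.ndarray, transform_state: Optional[str] = None) -> "ExpressionMatrix":
        return replace(
            self,
            values=values,
            transform_state=transform_state or self.transform_state,
        )


@dataclass
class TimeCourseSample:
    """One patient's ordered map timepoint (hours) -> ExpressionMatrix."""

    patient_id: str
    group: str
    matrices: Mapping[float, ExpressionMatrix]

    def __post_init__(self) -> None:
        self.matrices = dict(sorted(self.matrices.items()))
        missing = [t for t in TIMEPOINTS if t not in self.matrices]
        if missing:
            raise MissingTimepointError(
                f"sample {self.patient_id}: missing timepoints {missing}"
            )
        panels = {m.marker_names for m in self.matrices.values()}
        if len(panels) != 1:
            raise ValueError(
                f"sample {self.patient_id}: marker panels differ across timepoints"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return next(iter(self.matrices.values())).marker_names

    @property
    def timepoints(self) -> tuple[float, ...]:
        return tuple(self.matrices)


@dataclass
class ClinicalRecord:
    """Clinical metadata for one patient.

    ``group`` consistency with SLEDAI (aSLE <=> SLEDAI > 5, rSLE <=>
    SLEDAI <= 5) is checked by :func:`validate` which reports violations
    without silently fixing them.
    """

    patient_id: str
    group: str
    sledai: Optional[int] = None
    esr: Optional[float] = None
    outcome: str = "unknown"  # remission | flare | unknown

    def validate(self) -> list[str]:
        """Return a list of consistency violations (empty when clean)."""
        problems = []
        if self.group not in GROUPS:
            problems.append(f"{self.patient_id}: unknown group {self.group!r}")
        if self.sledai is not None:
            if self.sledai < 0:
                problems.append(f"{self.patient_id}: SLEDAI {self.sledai} < 0")
            if self.group == "aSLE" and self.sledai <= 5:
                problems.append(
                    f"{self.patient_id}: group aSLE but SLEDAI {self.sledai} <= 5"
                )
            if self.group == "rSLE" and self.sledai > 5:
                problems.append(
                    f"{self.patient_id}: group rSLE but SLEDAI {self.sledai} > 5"
                )
        if self.outcome not in ("remission", "flare", "unknown"):
            problems.append(f"{self.patient_id}: bad outcome {self.outcome!r}")
        return problems


@dataclass
class ModuleStats:
    """DNB statistics of one candidate marker module at one timepoint.

    sd_in : mean over members of the per-marker cell-level SD (arcsinh units)
    pcc_in : mean absolute pairwise Pearson correlation among members
    pcc_out : mean absolute Pearson correlation member <-> non-member
    index : composite DNB index sd_in * pcc_in / (pcc_out + eps)
    """

    members: tuple[str, ...]
    sd_in: float
    pcc_in: float
    pcc_out: float
    index: float = 0.0
    n_zero_variance_pairs: int = 0

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if len(self.members) < 2:
            raise ValueError("a module needs at least 2 members")
        if not (0.0 <= self.pcc_in <= 1.0 + 1e-12):
            raise ValueError(f"pcc_in {self.pcc_in} outside [0, 1]")
        if not (0.0 <= self.pcc_out <= 1.0 + 1e-12):
            raise ValueError(f"pcc_out {self.pcc_out} outside [0, 1]")
        if self.sd_in < 0:
            raise ValueError("sd_in must be nonnegative")


@dataclass
class RankedModule:
    """One candidate module with its trajectory and ranking key."""

    members: tuple[str, ...]
    stats: dict[float, ModuleStats]          # timepoint -> stats
    fold_change: float                        # max_t>0 I(t) / (I(0) + eps)
    peak_index: float                         # max_t>0 I(t)
    peak_time: float                          # argmax timepoint


@dataclass
class SampleDnbResult:
    """Per-sample DNB search output: ranked modules and top-k markers."""

    patient_id: str
    group: str
    ranked_modules: list[RankedModule]
    top_markers: tuple[str, ...]
    k: int
    baseline_hour: float = 0.0

    @property
    def best_module(self) -> RankedModule:
        return self.ranked_modules[0]

    @property
    def best_trajectory(self) -> dict[float, float]:
        return {t: s.index for t, s in self.best_module.stats.items()}


@dataclass
class CoreSet:
    """Consensus DNB core: markers recurring in per-sample top-k lists."""

    markers: tuple[str, ...]                  # by frequency desc, ties lexicographic
    frequency: dict[str, int]
    selection_rule: str                       # "top_m" | "min_frequency"
    parameter: int                            # m or f_min
    n_samples: int

    def __post_init__(self) -> None:
        bad = [m for m, f in self.frequency.items() if f > self.n_samples]
        if bad:
            raise ValueError(f"frequencies exceed sample count for {bad}")


@dataclass
class ScoreTrajectory:
    """Per-patient DNB score per timepoint plus the 2h-4h difference."""

    patient_id: str
    score: dict[float, float]
    delta: float
    prediction: str = "indeterminate"         # remission | flare | indeterminate
    threshold_used: float = 0.0

    def __post_init__(self) -> None:
        missing = [t for t in TIMEPOINTS if t not in self.score]
        if missing:
            raise MissingTimepointError(
                f"trajectory {self.patient_id}: missing hours {missing}"
            )
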