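"""Reading expression data and clinical metadata; standard CyTOF preprocessing.

Expression data arrive either as FCS 3.0/3.1 files or as delimited tables
(UTF-8, header row of marker names, cells as rows). Intensities are put on
the arcsinh scale (cofactor 5 by convention) before any variance-based
statistic; cells are subsampled to a common depth so per-timepoint SDs are
comparable.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import fcs
from .errors import (
    EmptyGroupError,
    FormatError,
    MissingTimepointError,
    NonNumericError,
    NoPanelOverlapError,
    TransformStateError,
    ZeroDenominatorError,
)
from .types import (
    RAW,
    TIMEPOINTS,
    ClinicalRecord,
    ExpressionMatrix,
    TimeCourseSample,
    arcsinh_state,
)

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0
#: Cells retained per (patient, timepoint) before DNB statistics, so SD
#: comparisons are not driven by unequal cell counts.
DEFAULT_SUBSAMPLE = 2000
#: Minimum cells for which cell-level SD / correlation are considered stable.
MIN_CELLS = 50


def read_expression(
    path: str | Path,
    format: str = "delimited",
    panel: Optional[Sequence[str]] = None,
    delimiter: str = ",",
    cluster_column: Optional[str] = None,
) -> ExpressionMatrix:
    """Load raw intensities from a delimited table or an FCS file.

    Channels absent from ``panel`` (when given) are dropped with a logged
    list. Rows containing missing entries are dropped and counted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")

    cluster_labels = None
    if format == "fcs":
        values, names = fcs.read_fcs(path)
        frame = pd.DataFrame(values, columns=names)
    elif format == "delimited":
        try:
            frame = pd.read_csv(path, sep=delimiter)
        except Exception as exc:  # pragma: no cover - pandas error surface
            raise FormatError(f"could not parse {path}: {exc}") from exc
        if frame.shape[1] < 1 or frame.shape[0] < 1:
            raise FormatError(f"{path}: empty table")
    else:
        raise ValueError(f"unknown format {format!r}")

    if cluster_column is not None:
        if cluster_column not in frame.columns:
            raise FormatError(f"{path}: no cluster column {cluster_column!r}")
        cluster_labels = frame[cluster_column].to_numpy()
        frame = frame.drop(columns=[cluster_column])

    if panel is not None:
        keep = [c for c in frame.columns if c in set(panel)]
        if not keep:
            raise NoPanelOverlapError(
                f"{path}: no overlap between file channels and panel"
            )
        dropped = [c for c in frame.columns if c not in set(panel)]
        if dropped:
            logger.info("%s: dropped %d channels not in panel: %s",
                        path.name, len(dropped), dropped)
        frame = frame[keep]

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad_cols = [
        c for c in frame.columns
        if numeric[c].isna().sum() > frame[c].isna().sum()
    ]
    if bad_cols:
        raise NonNumericError(f"{path}: non-numeric values in columns {bad_cols}")

    n_before = len(numeric)
    mask = ~numeric.isna().any(axis=1)
    if (~mask).any():
        logger.warning("%s: dropped %d rows with missing values",
                       path.name, n_before - int(mask.sum()))
    numeric = numeric[mask]
    if cluster_labels is not None:
        cluster_labels = cluster_labels[mask.to_numpy()]
    if numeric.empty:
        raise FormatError(f"{path}: no complete rows")

    return ExpressionMatrix(
        values=numeric.to_numpy(dtype=float),
        marker_names=tuple(numeric.columns),
        transform_state=RAW,
        cluster_labels=cluster_labels,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     delimiter: str = ",") -> None:
    """Write a matrix in the delimited dialect ``read_expression`` reads."""
    frame = pd.DataFrame(matrix.values, columns=list(matrix.marker_names))
    if matrix.cluster_labels is not None:
        frame["cluster"] = matrix.cluster_labels
    frame.to_csv(path, sep=delimiter, index=False)


def arcsinh_transform(matrix: ExpressionMatrix,
                      cofactor: float = DEFAULT_COFACTOR) -> ExpressionMatrix:
    """Apply x -> asinh(x / cofactor) to every intensity.

    The transform compresses high intensities while staying ~linear near
    zero; negative raw values (possible after compensation) map to negative
    transformed values and are retained. Double transformation is an error.
    """
    if matrix.transform_state != RAW:
        raise TransformStateError(
            f"matrix already transformed ({matrix.transform_state})"
        )
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return matrix.with_values(
        np.arcsinh(matrix.values / cofactor),
        transform_state=arcsinh_state(cofactor),
    )


def subsample_cells(matrix: ExpressionMatrix, n: int = DEFAULT_SUBSAMPLE,
                    seed: int = 0) -> ExpressionMatrix:
    """Uniformly subsample to ``n`` cells without replacement (seeded).

    Matrices with at most ``n`` cells pass through unchanged (logged).
    """
    if n < MIN_CELLS:
        raise ValueError(
            f"subsample size {n} < {MIN_CELLS}: downstream SD/correlation "
            "statistics would be unstable"
        )
    if matrix.n_cells <= n:
        logger.info("matrix has %d <= %d cells; not subsampled",
                    matrix.n_cells, n)
        return matrix
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(matrix.n_cells, size=n, replace=False))
    labels = None if matrix.cluster_labels is None else matrix.cluster_labels[rows]
    out = matrix.with_values(matrix.values[rows])
    out.cluster_labels = labels
    return out


def cluster_abundance(
    matrix: ExpressionMatrix,
    reference_clusters: Optional[Sequence] = None,
) -> dict:
    """Frequency of each cluster label among total cells.

    Frequencies sum to 1 over observed clusters. Clusters from
    ``reference_clusters`` with no cells are reported as 0.0.
    """
    if matrix.cluster_labels is None:
        raise ValueError("matrix has no cluster labels")
    labels, counts = np.unique(matrix.cluster_labels, return_counts=True)
    freq = {lab: cnt / matrix.n_cells for lab, cnt in zip(labels, counts)}
    if reference_clusters is not None:
        for lab in reference_clusters:
            freq.setdefault(lab, 0.0)
    return freq


def group_ratio(per_patient_values: Mapping[str, float],
                groups: Mapping[str, str], g1: str, g2: str) -> float:
    """Ratio of group means: mean over g1 patients / mean over g2 patients."""
    v1 = [v for p, v in per_patient_values.items() if groups.get(p) == g1]
    v2 = [v for p, v in per_patient_values.items() if groups.get(p) == g2]
    if not v1:
        raise EmptyGroupError(f"group {g1!r} has no patients with values")
    if not v2:
        raise EmptyGroupError(f"group {g2!r} has no patients with values")
    m2 = float(np.mean(v2))
    if m2 == 0.0:
        raise ZeroDenominatorError(f"group {g2!r} mean is zero")
    return float(np.mean(v1)) / m2


def load_sample(
    files: Mapping[float, str | Path],
    patient_id: str,
    group: str,
    format: str = "delimited",
    panel: Optional[Sequence[str]] = None,
    cofactor: float = DEFAULT_COFACTOR,
    subsample: Optional[int] = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> TimeCourseSample:
    """Read, transform and subsample all five timepoints of one patient.

    Missing timepoints are a hard error: the 2h-4h score difference needs
    both hours and trajectories need all five for ranking.
    """
    missing = [t for t in TIMEPOINTS if t not in files]
    if missing:
        raise MissingTimepointError(
            f"sample {patient_id}: no files for timepoints {missing}"
        )
    matrices = {}
    for i, t in enumerate(TIMEPOINTS):
        m = read_expression(files[t], format=format, panel=panel)
        m = arcsinh_transform(m, cofactor=cofactor)
        if subsample is not None:
            m = subsample_cells(m, n=subsample, seed=seed * 1000 + i)
        matrices[t] = m
    return TimeCourseSample(patient_id=patient_id, group=group,
                            matrices=matrices)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest: columns patient_id, group, timepoint, path."""
    frame = pd.read_csv(path)
    required = {"patient_id", "group", "timepoint", "path"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"manifest {path}: missing columns {sorted(missing)}")
    return frame


def load_cohort(
    manifest_path: str | Path,
    format: str = "delimited",
    panel: Optional[Sequence[str]] = None,
    cofactor: float = DEFAULT_COFACTOR,
    subsample: Optional[int] = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> list[TimeCourseSample]:
    """Load every patient listed in a cohort manifest."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    samples = []
    for pid, sub in manifest.groupby("patient_id", sort=True):
        files = {
            float(row.timepoint): root / row.path for row in sub.itertuples()
        }
        group = sub["group"].iloc[0]
        samples.append(
            load_sample(files, patient_id=str(pid), group=group,
                        format=format, panel=panel, cofactor=cofactor,
                        subsample=subsample, seed=seed)
        )
    return samples


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical table (patient_id, group, sledai, esr, outcome).

    Group/SLEDAI inconsistencies are logged as warnings, never silently
    repaired.
    """
    frame = pd.read_csv(path)
    required = {"patient_id", "group"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"clinical {path}: missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples():
        sledai = getattr(row, "sledai", None)
        sledai = None if sledai is None or pd.isna(sledai) else int(sledai)
        esr = getattr(row, "esr", None)
        esr = None if esr is None or pd.isna(esr) else float(esr)
        outcome = getattr(row, "outcome", "unknown")
        outcome = "unknown" if pd.isna(outcome) else str(outcome)
        rec = ClinicalRecord(patient_id=str(row.patient_id), group=row.group,
                             sledai=sledai, esr=esr, outcome=outcome)
        for problem in rec.validate():
            logger.warning("clinical inconsistency: %s", problem)
        records.append(rec)
    return records
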