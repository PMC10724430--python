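"""Synthetic cohorts of single-cell protein time courses with a planted DNB.

Cells are drawn from a multivariate normal on the arcsinh intensity scale
(a Gaussian copula: arcsinh-transformed CyTOF intensities are approximately
continuous, and Gaussianity makes the planted correlation/SD targets
exact). A module of markers is planted whose member SD and intra-module
correlation rise toward a transition timepoint (default 2 h of IL-2
stimulation) while their correlation with the background drops — the
defining signature of a dynamic network biomarker.

Per-patient response amplitude scales the planted rho_in/sigma_in
trajectories toward the unstimulated baseline, emulating the blunted IL-2
response of active disease; the latent 2h-4h score difference, computed by
the real scoring machinery on the noiseless population covariance, drives
both the simulated clinical severity (SLEDAI, ESR) and the remission/flare
outcome through a logistic link.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .core import PanelSummary
from .errors import AbsentTruthError, NotPositiveSemidefiniteError
from .ingest import DEFAULT_COFACTOR
from .types import (
    TIMEPOINTS,
    ClinicalRecord,
    ExpressionMatrix,
    TimeCourseSample,
    arcsinh_state,
)

#: Response amplitude at which the outcome link is centred: the latent
#: 2h-4h score difference of a patient at the aSLE/rSLE boundary.
REFERENCE_AMPLITUDE = 0.45

#: Per-group response-amplitude ranges (uniform draws). Healthy controls
#: respond almost uniformly; active SLE has the most blunted response;
#: remission SLE sits in between with the widest heterogeneity.
DEFAULT_GROUP_EFFECTS: dict[str, tuple[float, float]] = {
    "HC": (0.85, 1.0),
    "aSLE": (0.1, 0.45),
    "rSLE": (0.45, 0.9),
}

_PSD_TOL = 1e-8


@dataclass
class OutcomeLink:
    """Logistic link from the latent 2h-4h score difference to outcome.

    P(remission) = logistic(slope * (delta - delta0) + N(0, noise_sd)),
    with delta0 the latent difference at the reference amplitude.
    slope = inf gives the deterministic sign rule.
    """

    slope: float = 3.0
    noise_sd: float = 0.2


@dataclass
class SimulationParams:
    """Full specification of one synthetic scenario.

    Correlation/SD trajectories are literal per-timepoint vectors (aligned
    with ``timepoints``) so the planted truth is unambiguous. Defaults
    plant a 4-marker module among 25 whose intra-correlation climbs from
    the 0.05 background to 0.85 at the 2 h transition while member SD
    triples and module-background correlation falls from the background
    level to 0.02. Note a geometric constraint on uniform block
    correlation structures: roughly rho_out <= sqrt(rho_in * rho_bg), so
    a module can only decouple from (never exceed) the coupling implied by
    its own intra-correlation; violations are rejected by the PSD check.
    """

    n_markers: int = 25
    module_markers: tuple[int, ...] = (3, 8, 12, 19)   # 1-based indices
    n_cells: int = 2000
    timepoints: tuple[float, ...] = TIMEPOINTS
    rho_in: tuple[float, ...] = (0.05, 0.25, 0.5, 0.85, 0.3)
    rho_bg: float = 0.05
    sigma_in: tuple[float, ...] = (1.0, 1.5, 2.2, 3.0, 1.5)
    sigma_bg: float = 1.0
    rho_out: tuple[float, ...] = (0.05, 0.045, 0.035, 0.02, 0.04)
    transition_time: float = 2.0
    outcome_link: OutcomeLink = field(default_factory=OutcomeLink)
    location: float = 2.0          # shift to a nonnegative arcsinh scale
    cofactor: float = DEFAULT_COFACTOR
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_markers = tuple(sorted(self.module_markers))
        self.timepoints = tuple(self.timepoints)
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if not set(self.module_markers) <= set(range(1, self.n_markers + 1)):
            raise ValueError("module_markers must lie in 1..n_markers")
        if len(self.module_markers) < 2:
            raise ValueError("planted module needs at least 2 markers")
        if self.n_markers - len(self.module_markers) < 2:
            raise ValueError("need at least 2 background markers")
        for name in ("rho_in", "sigma_in", "rho_out"):
            vec = getattr(self, name)
            if len(vec) != len(self.timepoints):
                raise ValueError(
                    f"{name} has {len(vec)} entries for "
                    f"{len(self.timepoints)} timepoints"
                )
        if self.transition_time not in self.timepoints:
            raise ValueError("transition_time must be one of the timepoints")
        # construction-time PSD check at full and zero response amplitude
        for amplitude in (1.0, 0.0):
            for t in self.timepoints:
                self.correlation_matrix(t, amplitude=amplitude)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(f"M{i:02d}" for i in range(1, self.n_markers + 1))

    @property
    def module_marker_names(self) -> tuple[str, ...]:
        return tuple(f"M{i:02d}" for i in self.module_markers)

    def _t_index(self, t: float) -> int:
        return self.timepoints.index(t)

    def _scaled(self, vec: Sequence[float], t: float, amplitude: float) -> float:
        """Trajectory value at t with response amplitude a: the excursion
        from the unstimulated baseline is scaled by a."""
        i = self._t_index(t)
        return vec[0] + amplitude * (vec[i] - vec[0])

    def correlation_matrix(self, t: float, amplitude: float = 1.0) -> np.ndarray:
        """Block correlation matrix at timepoint t (PSD-checked)."""
        p = self.n_markers
        mem = np.array(self.module_markers) - 1
        out = np.setdiff1d(np.arange(p), mem)
        r_in = self._scaled(self.rho_in, t, amplitude)
        r_out = self._scaled(self.rho_out, t, amplitude)
        R = np.full((p, p), self.rho_bg)
        R[np.ix_(mem, mem)] = r_in
        R[np.ix_(mem, out)] = r_out
        R[np.ix_(out, mem)] = r_out
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R).min() < -_PSD_TOL:
            raise NotPositiveSemidefiniteError(
                f"correlation specification at t={t:g} h is not positive "
                f"semi-definite (rho_in={r_in:g}, rho_out={r_out:g}, "
                f"rho_bg={self.rho_bg:g})"
            )
        return R

    def sd_vector(self, t: float, amplitude: float = 1.0) -> np.ndarray:
        sd = np.full(self.n_markers, self.sigma_bg, dtype=float)
        sd[np.array(self.module_markers) - 1] = self._scaled(
            self.sigma_in, t, amplitude
        )
        return sd


def _substream(seed: int, patient_index: int, slot: int) -> np.random.Generator:
    """Counter-scheme substream: one stream per (patient, slot).

    Slots 0..len(timepoints)-1 are the per-timepoint cell draws; slot 100
    is the patient's clinical/outcome stream. Adding a patient to a cohort
    never perturbs the draws of existing patients.
    """
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(patient_index, slot))
    )


def simulate_sample(
    params: SimulationParams,
    patient_id: str,
    group: str = "HC",
    amplitude: float = 1.0,
    patient_index: int = 0,
) -> TimeCourseSample:
    """Draw one patient's five-timepoint expression matrices.

    Values live on the arcsinh scale (shifted by ``params.location``);
    matrices are reproducible from (params.seed, patient_index).
    """
    matrices = {}
    state = arcsinh_state(params.cofactor)
    for slot, t in enumerate(params.timepoints):
        R = params.correlation_matrix(t, amplitude=amplitude)
        sd = params.sd_vector(t, amplitude=amplitude)
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            # PSD but singular: tiny diagonal jitter for factorization only
            L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
        rng = _substream(params.seed, patient_index, slot)
        z = rng.standard_normal((params.n_cells, params.n_markers))
        values = z @ L.T * sd + params.location
        matrices[t] = ExpressionMatrix(
            values=values, marker_names=params.marker_names,
            transform_state=state,
        )
    return TimeCourseSample(patient_id=patient_id, group=group,
                            matrices=matrices)


def population_scores(params: SimulationParams,
                      amplitude: float = 1.0) -> dict[float, float]:
    """Latent DNB score of the planted module at each timepoint, computed
    by the real scoring machinery on the noiseless population statistics
    (independent of cell-sampling noise)."""
    scores = {}
    for t in params.timepoints:
        summary = PanelSummary.from_population(
            params.marker_names,
            params.correlation_matrix(t, amplitude=amplitude),
            params.sd_vector(t, amplitude=amplitude),
        )
        scores[t] = summary.module_stats(params.module_marker_names).index
    return scores


def latent_delta(params: SimulationParams, amplitude: float = 1.0,
                 t_a: float = 2.0, t_b: float = 4.0) -> float:
    s = population_scores(params, amplitude=amplitude)
    return s[t_a] - s[t_b]


@dataclass
class SyntheticCohort:
    """Simulated samples plus clinical table and the generating truth."""

    samples: list[TimeCourseSample]
    clinical: list[ClinicalRecord]
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        ids_s = {s.patient_id for s in self.samples}
        ids_c = {c.patient_id for c in self.clinical}
        if ids_s != ids_c:
            raise ValueError("samples and clinical records must match 1:1")


def _simulate_severity(rng: np.random.Generator, group: str,
                       amplitude: float) -> tuple[Optional[int], Optional[float]]:
    """SLEDAI and ESR decreasing in response amplitude within each SLE
    group, respecting aSLE > 5 >= rSLE."""
    if group == "HC":
        return 0, float(np.clip(8 + rng.normal(0, 3), 2, 20))
    if group == "aSLE":
        lo, hi = DEFAULT_GROUP_EFFECTS["aSLE"]
        frac = (hi - amplitude) / (hi - lo)       # 0 mild .. 1 severe
        sledai = int(np.clip(round(6 + 12 * frac + rng.normal(0, 1)), 6, 30))
    else:
        lo, hi = DEFAULT_GROUP_EFFECTS["rSLE"]
        frac = (hi - amplitude) / (hi - lo)
        sledai = int(np.clip(round(5 * frac + rng.normal(0, 0.7)), 0, 5))
    esr = float(np.clip(8 + 2.5 * sledai + rng.normal(0, 4), 2, 140))
    return sledai, esr


def simulate_cohort(
    params: SimulationParams,
    n_per_group: Mapping[str, int] = None,
    group_effects: Mapping[str, tuple[float, float]] = None,
) -> SyntheticCohort:
    """Generate a full cohort with clinical records and outcome labels.

    Each patient gets a response amplitude drawn uniformly from their
    group's range; SLE outcomes (remission vs flare) follow the logistic
    link on the latent 2h-4h score difference, centred at the difference
    of a reference patient at the aSLE/rSLE amplitude boundary.
    """
    n_per_group = dict(n_per_group or {"HC": 4, "aSLE": 6, "rSLE": 6})
    group_effects = dict(group_effects or DEFAULT_GROUP_EFFECTS)
    for g, n in n_per_group.items():
        if n < 0:
            raise ValueError(f"n_per_group[{g!r}] must be >= 0")

    delta0 = latent_delta(params, amplitude=REFERENCE_AMPLITUDE)
    link = params.outcome_link

    samples: list[TimeCourseSample] = []
    clinical: list[ClinicalRecord] = []
    amplitudes: dict[str, float] = {}
    deltas: dict[str, float] = {}
    patient_index = 0
    for group in ("HC", "aSLE", "rSLE"):
        for j in range(n_per_group.get(group, 0)):
            pid = f"{group}{j + 1:02d}"
            rng = _substream(params.seed, patient_index, 100)
            lo, hi = group_effects[group]
            amplitude = float(rng.uniform(lo, hi))
            sample = simulate_sample(params, pid, group=group,
                                     amplitude=amplitude,
                                     patient_index=patient_index)
            d = latent_delta(params, amplitude=amplitude)
            sledai, esr = _simulate_severity(rng, group, amplitude)
            if group == "HC":
                outcome = "unknown"
            elif math.isinf(link.slope):
                outcome = "remission" if d >= delta0 else "flare"
            else:
                p_rem = float(expit(link.slope * (d - delta0)
                                    + rng.normal(0, link.noise_sd)))
                outcome = "remission" if rng.uniform() < p_rem else "flare"
            samples.append(sample)
            clinical.append(ClinicalRecord(
                patient_id=pid, group=group, sledai=sledai, esr=esr,
                outcome=outcome,
            ))
            amplitudes[pid] = amplitude
            deltas[pid] = d
            patient_index += 1

    truth = {
        "params": params,
        "module_markers": params.module_marker_names,
        "amplitudes": amplitudes,
        "latent_delta": deltas,
        "delta0": delta0,
    }
    return SyntheticCohort(samples=samples, clinical=clinical, truth=truth)


def planted_truth(cohort: SyntheticCohort) -> dict:
    """Planted module membership and latent score differences (read-only).

    Cohorts built from real data carry no truth; asking for one raises
    :class:`AbsentTruthError` rather than returning an empty record.
    """
    if cohort.truth is None:
        raise AbsentTruthError("cohort carries no planted truth (real data?)")
    return cohort.truth


# ---------------------------------------------------------------------------
# on-disk round trip in the dialect the ingest module reads


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort as delimited tables plus manifest and clinical CSVs.

    Matrices are emitted on the RAW intensity scale (sinh-inverting the
    generated arcsinh values) so the standard ingest path — arcsinh with
    the same cofactor — reproduces the generated values exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sample in cohort.samples:
        for t, m in sample.matrices.items():
            cofactor = float(m.transform_state.split("(")[1].rstrip(")"))
            raw = np.sinh(m.values) * cofactor
            fname = f"{sample.patient_id}_t{t:g}h.csv"
            header = ",".join(m.marker_names)
            np.savetxt(outdir / fname, raw, delimiter=",", header=header,
                       comments="", fmt="%.10g")
            manifest_rows.append(
                f"{sample.patient_id},{sample.group},{t:g},{fname}"
            )
    manifest = outdir / "manifest.csv"
    manifest.write_text(
        "patient_id,group,timepoint,path\n" + "\n".join(manifest_rows) + "\n"
    )
    lines = ["patient_id,group,sledai,esr,outcome"]
    for rec in cohort.clinical:
        sledai = "" if rec.sledai is None else rec.sledai
        esr = "" if rec.esr is None else f"{rec.esr:.2f}"
        lines.append(f"{rec.patient_id},{rec.group},{sledai},{esr},{rec.outcome}")
    (outdir / "clinical.csv").write_text("\n".join(lines) + "\n")

    params = cohort.truth["params"] if cohort.truth else None
    meta = {
        "cofactor": params.cofactor if params else DEFAULT_COFACTOR,
        "seed": params.seed if params else None,
        "n_markers": params.n_markers if params else None,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return manifest
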