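"""Planted-truth validation harness.

Runs the full pipeline on synthetic cohorts with known ground truth and
measures recovery, oracle agreement, prediction accuracy and the sign of
the clinical correlation. These are the study conditions under which the
pipeline is validated end-to-end; the same functions back the test suite
and the reproduction script.

Study conditions (defaults): cohorts of 12 SLE samples (6 active, 6
remission), 25 markers, a planted 4-marker module (intra-correlation
0.05 -> 0.85 at the 2 h transition, member SD 1 -> 3, module-background
correlation decoupling 0.05 -> 0.02), 2000 cells per (patient, timepoint),
evaluated over 50 seeded replicates.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from . import pipeline, scoring
from .core import EPSILON, exhaustive_best_module, rank_modules
from .simulate import (
    OutcomeLink,
    SimulationParams,
    planted_truth,
    simulate_cohort,
    simulate_sample,
)
from .types import ModuleStats

N_SEEDS = 50
SLE_COHORT = {"aSLE": 6, "rSLE": 6}


def _seed(base_seed: int, i: int) -> int:
    return (base_seed + 1_000_003 * i) % (2**31 - 1)


def planted_core_recovery(
    n_seeds: int = N_SEEDS,
    base_seed: int = 0,
    n_per_group: dict | None = None,
) -> dict:
    """Recovery of the planted module by the consensus top-4 core.

    For each seed: simulate a 12-sample SLE cohort, run per-sample module
    ranking, pool top-5 markers, select the 4 most frequent, and count the
    overlap with the planted 4-marker module.
    """
    overlaps = []
    for i in range(n_seeds):
        params = SimulationParams(seed=_seed(base_seed, i))
        cohort = simulate_cohort(params, n_per_group=n_per_group or SLE_COHORT)
        results = pipeline.rank_cohort(cohort.samples)
        core = pipeline.consensus_core(results, rule="top_m", m=4)
        planted = set(planted_truth(cohort)["module_markers"])
        overlaps.append(len(planted & set(core.markers)))
    overlaps = np.array(overlaps)
    return {
        "overlaps": overlaps,
        "recovery_rate": float((overlaps >= 3).mean()),
        "mean_overlap": float(overlaps.mean()),
        "n_seeds": n_seeds,
    }


def oracle_agreement(
    n_fixtures: int = 20,
    base_seed: int = 0,
    n_cells: int = 5000,
) -> dict:
    """Agreement between the clustering-based search and exhaustive
    enumeration on 8-marker panels (where all subsets can be scored).

    Both sides use the identical ranking key; agreement is on the argmax.
    """
    agree = 0
    for i in range(n_fixtures):
        params = SimulationParams(
            n_markers=8, module_markers=(2, 5, 7), n_cells=n_cells,
            seed=_seed(base_seed, 7000 + i),
        )
        sample = simulate_sample(params, f"fix{i}", amplitude=1.0)
        best = rank_modules(sample).best_module.members
        oracle = exhaustive_best_module(sample).members
        agree += best == oracle
    return {"n_agree": agree, "n_fixtures": n_fixtures,
            "agreement_rate": agree / n_fixtures}


def composite_index_laws(
    n_grid: int = 12, scale_factors: tuple[float, ...] = (2.0, 3.5, 10.0)
) -> dict:
    """Monotonicity of I on a parameter grid and scale equivariance.

    Scale equivariance is exercised on data: multiplying the member
    columns of a matrix by c must multiply I by c (relative error below
    1e-8) while leaving pcc_in/pcc_out unchanged.
    """
    from .core import composite_index, module_stats
    from .types import ExpressionMatrix

    violations = 0
    grid = np.linspace(0.05, 0.95, n_grid)
    sds = np.linspace(0.1, 3.0, n_grid)
    for sd_lo, sd_hi in zip(sds[:-1], sds[1:]):
        for r in grid:
            a = ModuleStats(("a", "b"), sd_in=sd_lo, pcc_in=r, pcc_out=r / 2)
            b = ModuleStats(("a", "b"), sd_in=sd_hi, pcc_in=r, pcc_out=r / 2)
            violations += not composite_index(b) > composite_index(a)
    for r_lo, r_hi in zip(grid[:-1], grid[1:]):
        a = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=r_lo, pcc_out=0.3)
        b = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=r_hi, pcc_out=0.3)
        violations += not composite_index(b) > composite_index(a)
        a = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=0.5, pcc_out=r_lo)
        b = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=0.5, pcc_out=r_hi)
        violations += not composite_index(b) < composite_index(a)

    rng = np.random.default_rng(12345)
    X = rng.standard_normal((400, 6)) @ rng.standard_normal((6, 6))
    names = tuple("ABCDEF")
    members = ("A", "B", "C")
    base = module_stats(ExpressionMatrix(X, names), members)
    max_rel_err = 0.0
    for c in scale_factors:
        Y = X.copy()
        Y[:, :3] *= c
        scaled = module_stats(ExpressionMatrix(Y, names), members)
        max_rel_err = max(
            max_rel_err,
            abs(scaled.index - c * base.index) / (c * base.index),
            abs(scaled.pcc_in - base.pcc_in),
            abs(scaled.pcc_out - base.pcc_out),
        )
    return {"monotonicity_violations": violations,
            "scale_equivariance_max_rel_err": max_rel_err}


def _cohort_prediction_accuracy(params: SimulationParams,
                                n_per_group: dict) -> float:
    """Full-pipeline accuracy against simulated outcomes, thresholding the
    empirical 2h-4h difference at the generator's recorded link centre."""
    cohort = simulate_cohort(params, n_per_group=n_per_group)
    results = pipeline.rank_cohort(cohort.samples)
    core = pipeline.consensus_core(results, rule="top_m", m=4)
    truth = planted_truth(cohort)
    trajectories = pipeline.score_cohort(cohort.samples, core,
                                         threshold=truth["delta0"])
    outcomes = {c.patient_id: c.outcome for c in cohort.clinical}
    scored = [(t.prediction, outcomes[t.patient_id]) for t in trajectories
              if outcomes[t.patient_id] in ("remission", "flare")]
    return float(np.mean([p == o for p, o in scored]))


def outcome_prediction(
    n_seeds: int = N_SEEDS,
    slope: float = 3.0,
    noise_sd: float = 0.2,
    base_seed: int = 0,
) -> dict:
    """Per-seed full-pipeline remission/flare prediction accuracy."""
    accs = []
    for i in range(n_seeds):
        params = SimulationParams(
            seed=_seed(base_seed, 3000 + i),
            outcome_link=OutcomeLink(slope=slope, noise_sd=noise_sd),
        )
        accs.append(_cohort_prediction_accuracy(params, SLE_COHORT))
    accs = np.array(accs)
    half = 1.96 * accs.std(ddof=1) / math.sqrt(n_seeds)
    return {
        "accuracies": accs,
        "mean_accuracy": float(accs.mean()),
        "ci95": (float(accs.mean() - half), float(accs.mean() + half)),
        "n_seeds": n_seeds,
    }


def delta_severity_sign(n_seeds: int = N_SEEDS, base_seed: int = 0) -> dict:
    """Sign of Spearman rho between the empirical 2h-4h score difference
    and simulated severity (SLEDAI, ESR) across SLE patients.

    The generator links higher severity to a blunted late response, so the
    correlation should be negative — a direction, not a magnitude.
    """
    neg_sledai = neg_esr = 0
    rhos = []
    for i in range(n_seeds):
        params = SimulationParams(seed=_seed(base_seed, 5000 + i))
        cohort = simulate_cohort(params, n_per_group=SLE_COHORT)
        results = pipeline.rank_cohort(cohort.samples)
        core = pipeline.consensus_core(results, rule="top_m", m=4)
        trajectories = pipeline.score_cohort(cohort.samples, core)
        deltas = {t.patient_id: t.delta for t in trajectories}
        rho_s, _ = scoring.clinical_correlation(deltas, cohort.clinical,
                                                "SLEDAI")
        rho_e, _ = scoring.clinical_correlation(deltas, cohort.clinical,
                                                "ESR")
        neg_sledai += rho_s < 0
        neg_esr += rho_e < 0
        rhos.append(rho_s)
    return {
        "negative_rate_sledai": neg_sledai / n_seeds,
        "negative_rate_esr": neg_esr / n_seeds,
        "mean_rho_sledai": float(np.mean(rhos)),
        "n_seeds": n_seeds,
    }
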