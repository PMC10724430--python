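"""End-to-end driver: per-sample DNB search -> consensus core -> scoring.

This is the composition the analysis scripts, the command-line interface
and the validation harness all share.
"""
from __future__ import annotations

from typing import Optional, Sequence

from . import consensus, core, scoring
from .types import ClinicalRecord, CoreSet, SampleDnbResult, ScoreTrajectory, TimeCourseSample


def rank_cohort(
    samples: Sequence[TimeCourseSample],
    baseline_hour: float = 0.0,
    min_size: int = 2,
    max_size: int = 8,
    k: int = core.DEFAULT_TOP_K,
) -> list[SampleDnbResult]:
    """Run the per-sample module search and ranking for a whole cohort."""
    return [
        core.rank_modules(s, baseline_hour=baseline_hour, min_size=min_size,
                          max_size=max_size, k=k)
        for s in samples
    ]


def consensus_core(
    results: Sequence[SampleDnbResult],
    rule: str = "top_m",
    m: int = consensus.DEFAULT_M,
    f_min: int = consensus.DEFAULT_F_MIN,
    k: int = core.DEFAULT_TOP_K,
    restrict_to_group: Optional[Sequence[str]] = None,
) -> CoreSet:
    """Pool per-sample top markers and select the consensus core."""
    freq = consensus.marker_frequency(results, k=k,
                                      restrict_to_group=restrict_to_group)
    n = (len(results) if restrict_to_group is None
         else sum(r.group in set(restrict_to_group) for r in results))
    return consensus.select_core(freq, rule=rule, m=m, f_min=f_min,
                                 n_samples=n)


def score_cohort(
    samples: Sequence[TimeCourseSample],
    core_set: CoreSet | Sequence[str],
    threshold: float = 0.0,
    indeterminate_band: float = 0.0,
) -> list[ScoreTrajectory]:
    """Score every sample on a fixed core set."""
    return [
        scoring.score_trajectory(s, core_set, threshold=threshold,
                                 indeterminate_band=indeterminate_band)
        for s in samples
    ]


def run_pipeline(
    samples: Sequence[TimeCourseSample],
    clinical: Sequence[ClinicalRecord],
    rule: str = "top_m",
    m: int = consensus.DEFAULT_M,
    f_min: int = consensus.DEFAULT_F_MIN,
    k: int = core.DEFAULT_TOP_K,
    threshold: float = 0.0,
    restrict_to_group: Optional[Sequence[str]] = None,
) -> dict:
    """Full analysis: ranking, consensus core, trajectories, cohort report."""
    results = rank_cohort(samples, k=k)
    core_set = consensus_core(results, rule=rule, m=m, f_min=f_min, k=k,
                              restrict_to_group=restrict_to_group)
    trajectories = score_cohort(samples, core_set, threshold=threshold)
    report = scoring.cohort_report(trajectories, clinical)
    return {
        "sample_results": results,
        "core": core_set,
        "trajectories": trajectories,
        "report": report,
    }
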