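"""Dynamic network biomarker statistics, candidate-module search and ranking.

A dynamic network biomarker (DNB) is a group of markers whose member
standard deviations and mutual correlations surge, while their correlation
with the rest of the panel drops, as the system approaches a critical
transition. The three conditions fold into one composite index

    I = sd_in * pcc_in / (pcc_out + eps)

where sd_in is the mean member SD, pcc_in the mean absolute pairwise
Pearson correlation inside the module and pcc_out the mean absolute
correlation between members and non-members. Per sample, candidate modules
are ranked by the surge of I relative to the unstimulated baseline.

The replicate unit for SD and Pearson r is the cell population of one
(patient, timepoint) after arcsinh transform and subsampling — the only
reading under which a per-sample, per-timepoint score is computable from a
single blood draw.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .types import (
    ExpressionMatrix,
    ModuleStats,
    RankedModule,
    SampleDnbResult,
    TimeCourseSample,
)

logger = logging.getLogger(__name__)

EPSILON = 1e-6
DEFAULT_TOP_K = 5


# ---------------------------------------------------------------------------
# panel-level summary: correlation matrix + SD vector, computed once


@dataclass
class PanelSummary:
    """Per-timepoint sufficient statistics for every module statistic.

    Pairs involving a zero-variance marker get r = 0 (logged count) rather
    than being dropped, keeping pair-average denominators stable across
    timepoints.
    """

    marker_names: tuple[str, ...]
    corr: np.ndarray          # p x p, |r| NOT applied; zero-variance rows -> 0
    sd: np.ndarray            # p, ddof=1
    n_zero_variance: int

    @classmethod
    def from_matrix(cls, m: ExpressionMatrix) -> "PanelSummary":
        if m.n_cells < 2:
            raise ValueError("need at least 2 cells for SD/correlation")
        sd = m.values.std(axis=0, ddof=1)
        zero = sd == 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(m.values, rowvar=False)
        corr = np.atleast_2d(corr)
        corr[~np.isfinite(corr)] = 0.0
        if zero.any():
            corr[zero, :] = 0.0
            corr[:, zero] = 0.0
            logger.info("%d zero-variance markers; their pairs contribute r=0",
                        int(zero.sum()))
        np.fill_diagonal(corr, 1.0)
        return cls(marker_names=m.marker_names, corr=corr, sd=sd,
                   n_zero_variance=int(zero.sum()))

    @classmethod
    def from_population(cls, marker_names: Sequence[str], corr: np.ndarray,
                        sd: np.ndarray) -> "PanelSummary":
        """Wrap a known (noiseless) correlation matrix and SD vector."""
        return cls(marker_names=tuple(marker_names),
                   corr=np.asarray(corr, dtype=float),
                   sd=np.asarray(sd, dtype=float), n_zero_variance=0)

    def module_stats(self, members: Sequence[str],
                     epsilon: float = EPSILON) -> ModuleStats:
        names = list(self.marker_names)
        idx = {n: i for i, n in enumerate(names)}
        missing = [m for m in members if m not in idx]
        if missing:
            raise KeyError(f"module members not in panel: {missing}")
        mem = np.array([idx[m] for m in members], dtype=int)
        if len(mem) < 2:
            raise ValueError("a module needs at least 2 members")
        out = np.array([i for i in range(len(names)) if i not in set(mem)],
                       dtype=int)
        if len(out) < 2:
            raise ValueError("need at least 2 non-members for pcc_out")

        sd_in = float(self.sd[mem].mean())
        abs_r = np.abs(self.corr)
        iu = np.triu_indices(len(mem), k=1)
        pcc_in = float(abs_r[np.ix_(mem, mem)][iu].mean())
        pcc_out = float(abs_r[np.ix_(mem, out)].mean())
        n_zero_pairs = 0
        if self.n_zero_variance:
            zero = self.sd == 0.0
            zin = zero[mem]
            n_zero_pairs = int(
                (zin[iu[0]] | zin[iu[1]]).sum()
                + (zin[:, None] | zero[out][None, :]).sum()
            )
        stats = ModuleStats(
            members=tuple(members), sd_in=sd_in, pcc_in=min(pcc_in, 1.0),
            pcc_out=min(pcc_out, 1.0), n_zero_variance_pairs=n_zero_pairs,
        )
        stats.index = composite_index(stats, epsilon=epsilon)
        return stats


def module_stats(m: ExpressionMatrix, members: Sequence[str],
                 epsilon: float = EPSILON) -> ModuleStats:
    """DNB statistics (sd_in, pcc_in, pcc_out, I) of one module.

    Requires at least 50 cells, |members| >= 2 and >= 2 non-members.
    """
    if m.n_cells < 50:
        raise ValueError(f"only {m.n_cells} cells; need >= 50 for stable stats")
    return PanelSummary.from_matrix(m).module_stats(members, epsilon=epsilon)


def composite_index(s: ModuleStats, epsilon: float = EPSILON) -> float:
    """Composite DNB index I = sd_in * pcc_in / (pcc_out + epsilon).

    Strictly increasing in sd_in and pcc_in, strictly decreasing in
    pcc_out; epsilon guards the fully-decoupled-module limit pcc_out -> 0.
    """
    return s.sd_in * s.pcc_in / (s.pcc_out + epsilon)


# ---------------------------------------------------------------------------
# candidate-module search


def _subtree_clusters(Z: np.ndarray, p: int) -> list[frozenset]:
    """Leaf sets of every internal node of a linkage tree.

    These are exactly the clusters appearing at some cut height of the
    dendrogram (sizes 2..p).
    """
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(p)}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[p + step] = merged
        out.append(merged)
    return out


def candidate_modules(
    m: ExpressionMatrix | PanelSummary,
    min_size: int = 2,
    max_size: int = 8,
) -> list[tuple[str, ...]]:
    """Candidate marker modules from correlation-based hierarchical clustering.

    Average-linkage clustering on the distance 1 - |Pearson r|; the
    candidates are every dendrogram cluster whose size lies in
    [min_size, max_size] (and leaves >= 2 non-members), deduplicated and
    ordered by size then lexicographic member names.
    """
    summary = m if isinstance(m, PanelSummary) else PanelSummary.from_matrix(m)
    p = len(summary.marker_names)
    if p < 4:
        raise ValueError("need a panel of >= 4 markers")
    if (summary.sd == 0.0).all():
        warnings.warn("all markers constant: no candidate modules")
        return []
    dist = 1.0 - np.abs(summary.corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")

    cap = min(max_size, p - 2)  # keep >= 2 non-members for pcc_out
    names = summary.marker_names
    seen = set()
    result = []
    for cluster in _subtree_clusters(Z, p):
        if min_size <= len(cluster) <= cap and cluster not in seen:
            seen.add(cluster)
            result.append(tuple(sorted(names[i] for i in cluster)))
    result.sort(key=lambda mod: (len(mod), mod))
    return result


# ---------------------------------------------------------------------------
# per-sample ranking


def _ranking_key(rm: RankedModule) -> tuple:
    # larger fold-change first, then larger peak index, then lexicographic
    return (-rm.fold_change, -rm.peak_index, rm.members)


def rank_modules(
    sample: TimeCourseSample,
    baseline_hour: float = 0.0,
    min_size: int = 2,
    max_size: int = 8,
    k: int = DEFAULT_TOP_K,
    epsilon: float = EPSILON,
    candidates: Optional[Sequence[Sequence[str]]] = None,
) -> SampleDnbResult:
    """Rank candidate modules of one sample by their DNB-index surge.

    The candidate pool is the union of hierarchical-clustering candidates
    over all timepoints (a module that tightens only near the transition
    must still be found). Ranking key: the regularized index surge

        (max_{t>baseline} I(t) + c) / (I(baseline) + c)

    with ridge c = mean baseline marker SD, the index a null (background)
    module attains at baseline. The ridge matters: the raw ratio's
    denominator for a 2-member module rests on a single baseline
    correlation, and its sampling noise — not the module's dynamics —
    would otherwise decide the argmax. c is independent of the candidate
    list and scales with the data, so the ranking is scale-invariant and
    a sample with identical matrices at all timepoints has every surge
    exactly 1 (falling through to the tie-breakers: larger peak I(t),
    then lexicographic member names).
    """
    summaries = {
        t: PanelSummary.from_matrix(mat) for t, mat in sample.matrices.items()
    }
    if candidates is None:
        pool: dict[tuple, None] = {}
        for t in sample.timepoints:
            for mod in candidate_modules(summaries[t], min_size, max_size):
                pool.setdefault(mod, None)
        candidates = sorted(pool, key=lambda mod: (len(mod), mod))
    else:
        candidates = [tuple(c) for c in candidates]
    if not candidates:
        raise ValueError(f"sample {sample.patient_id}: no candidate modules")

    ridge = float(summaries[baseline_hour].sd.mean())
    ranked = []
    for members in candidates:
        stats = {t: summaries[t].module_stats(members, epsilon=epsilon)
                 for t in sample.timepoints}
        base = stats[baseline_hour].index
        post = {t: s.index for t, s in stats.items() if t > baseline_hour}
        peak_time = max(post, key=lambda t: (post[t], -t))
        peak = post[peak_time]
        denom = base + ridge
        ranked.append(RankedModule(
            members=members, stats=stats,
            fold_change=(peak + ridge) / (denom if denom > 0 else epsilon),
            peak_index=peak, peak_time=peak_time,
        ))
    ranked.sort(key=_ranking_key)

    top = _top_marker_list(ranked, summaries, baseline_hour, k, epsilon)
    return SampleDnbResult(
        patient_id=sample.patient_id, group=sample.group,
        ranked_modules=ranked, top_markers=top, k=k,
        baseline_hour=baseline_hour,
    )


def _sd_fold_change(summaries, marker: str, at: float, baseline: float,
                    epsilon: float) -> float:
    names = summaries[at].marker_names
    i = names.index(marker)
    return summaries[at].sd[i] / (summaries[baseline].sd[i] + epsilon)


def _top_marker_list(ranked, summaries, baseline_hour, k, epsilon):
    """Members of the best module ordered by SD fold-change at its peak
    timepoint, extended from next-ranked modules to exactly k markers."""
    panel = summaries[baseline_hour].marker_names
    k_eff = k
    if len(panel) < k:
        warnings.warn(f"panel of {len(panel)} markers < k={k}; "
                      "returning all markers")
        k_eff = len(panel)
    out: list[str] = []
    for rm in ranked:
        fresh = [m for m in rm.members if m not in out]
        fresh.sort(
            key=lambda m: (-_sd_fold_change(summaries, m, rm.peak_time,
                                            baseline_hour, epsilon), m)
        )
        out.extend(fresh)
        if len(out) >= k_eff:
            break
    return tuple(out[:k_eff])


def top_markers(result: SampleDnbResult, k: int = DEFAULT_TOP_K) -> tuple[str, ...]:
    """Top-k dynamical markers of a ranked sample (k <= the ranking's k)."""
    if k <= len(result.top_markers):
        return result.top_markers[:k]
    raise ValueError(
        f"ranking was computed with k={result.k}; cannot extend to k={k}"
    )


# ---------------------------------------------------------------------------
# exhaustive search (small panels): used as a cross-check of the
# clustering-based candidate search, never as the production path


def exhaustive_best_module(
    sample: TimeCourseSample,
    baseline_hour: float = 0.0,
    min_size: int = 2,
    max_size: int = 8,
    epsilon: float = EPSILON,
) -> RankedModule:
    """Best module over ALL marker subsets under the same ranking key.

    Feasible only for panels of ~10 markers or fewer.
    """
    panel = sample.marker_names
    cap = min(max_size, len(panel) - 2)
    all_subsets = [
        tuple(sorted(c))
        for size in range(min_size, cap + 1)
        for c in combinations(panel, size)
    ]
    result = rank_modules(sample, baseline_hour=baseline_hour,
                          epsilon=epsilon, candidates=all_subsets)
    return result.best_module
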