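"""Consensus DNB core selection across a cohort.

Each sample contributes its top-k dynamical markers; pooled frequencies
(count of samples whose top-k contains a marker) define the consensus
core, either as the m most frequent markers (default m = 4, the size that
robustly describes homeostasis) or as every marker with frequency >= f_min
(default 5).
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

from .types import CoreSet, SampleDnbResult

logger = logging.getLogger(__name__)

DEFAULT_M = 4
DEFAULT_F_MIN = 5


def marker_frequency(
    results: Sequence[SampleDnbResult],
    k: int = 5,
    restrict_to_group: Optional[Sequence[str]] = None,
) -> dict[str, int]:
    """Count, per marker, the samples whose top-k list contains it.

    ``restrict_to_group`` limits the pool (e.g. to SLE samples only). All
    results must have been ranked with the same k.
    """
    if not results:
        raise ValueError("no sample results to pool")
    ks = {r.k for r in results}
    if ks != {k}:
        raise ValueError(f"mixed top-k sizes {sorted(ks)}; expected k={k}")
    if restrict_to_group is not None:
        allowed = set(restrict_to_group)
        pool = [r for r in results if r.group in allowed]
        if not pool:
            logger.warning("group restriction %s matches no samples", allowed)
            return {}
    else:
        pool = list(results)
    freq: dict[str, int] = {}
    for r in pool:
        for m in r.top_markers:
            freq[m] = freq.get(m, 0) + 1
    return freq


def _ordered(freq: dict[str, int]) -> list[str]:
    # frequency descending, ties lexicographic
    return sorted(freq, key=lambda m: (-freq[m], m))


def select_core(
    freq: dict[str, int],
    rule: str = "top_m",
    m: int = DEFAULT_M,
    f_min: int = DEFAULT_F_MIN,
    n_samples: Optional[int] = None,
) -> CoreSet:
    """Select the consensus core from pooled marker frequencies.

    rule="top_m": the m most frequent markers, boundary ties broken
    lexicographically (and logged). rule="min_frequency": every marker
    with count >= f_min.
    """
    if not freq:
        raise ValueError("empty frequency map")
    if n_samples is None:
        n_samples = max(freq.values())
    order = _ordered(freq)

    if rule == "top_m":
        if m > len(order):
            logger.warning("m=%d exceeds %d distinct markers; returning all",
                           m, len(order))
            chosen = order
        else:
            chosen = order[:m]
            boundary = freq[chosen[-1]]
            tied_out = [x for x in order[len(chosen):] if freq[x] == boundary]
            if tied_out:
                logger.info(
                    "frequency tie at the selection boundary (count %d): "
                    "kept %s over %s lexicographically",
                    boundary,
                    [x for x in chosen if freq[x] == boundary], tied_out,
                )
        parameter = m
    elif rule == "min_frequency":
        chosen = [x for x in order if freq[x] >= f_min]
        if not chosen:
            logger.warning("no marker reaches frequency %d: empty core", f_min)
        parameter = f_min
    else:
        raise ValueError(f"unknown selection rule {rule!r}")

    return CoreSet(markers=tuple(chosen), frequency=dict(freq),
                   selection_rule=rule, parameter=parameter,
                   n_samples=n_samples)
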