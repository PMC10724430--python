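#!/usr/bin/env python
"""Consensus DNB core across the cohort.

Pools each sample's top-5 dynamical markers, counts per-marker frequencies
and selects the core two ways: the 4 most frequent markers (the scoring
core) and every marker appearing in at least 5 samples (the broad set).
"""
import json
from pathlib import Path

import pandas as pd

from dnbpipe import load_cohort, marker_frequency, rank_cohort, select_core

COHORT = Path("scratch/analysis/cohort/manifest.csv")
RESULTS = Path("results")


def main() -> None:
    samples = load_cohort(COHORT)
    results = rank_cohort(samples)
    freq = marker_frequency(results, k=5)
    top4 = select_core(freq, rule="top_m", m=4, n_samples=len(results))
    broad = select_core(freq, rule="min_frequency", f_min=5,
                        n_samples=len(results))

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["marker", "frequency"],
    ).to_csv(RESULTS / "marker_frequency.csv", index=False)
    (RESULTS / "core.json").write_text(json.dumps({
        "top4_core": list(top4.markers),
        "min_frequency_5_set": list(broad.markers),
        "n_samples": len(results),
    }, indent=2))

    print("marker frequencies (top 8):")
    for m, f in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:8]:
        print(f"  {m}: {f}/{len(results)}")
    print(f"top-4 scoring core: {', '.join(top4.markers)}")
    print(f"frequency>=5 set:   {', '.join(broad.markers)}")


if __name__ == "__main__":
    main()
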