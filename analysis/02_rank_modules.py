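#!/usr/bin/env python
"""Per-sample DNB module search.

Loads the simulated cohort back through the standard ingest path (raw
intensities -> arcsinh cofactor 5 -> 2000-cell subsample), searches
candidate modules per sample per timepoint, and ranks them by the
regularized surge of the composite index over the unstimulated baseline.
Writes the per-sample best modules and top-5 marker lists.
"""
from pathlib import Path

import pandas as pd

from dnbpipe import load_cohort, rank_cohort

COHORT = Path("scratch/analysis/cohort/manifest.csv")
RESULTS = Path("results")


def main() -> None:
    samples = load_cohort(COHORT)
    results = rank_cohort(samples)
    rows = []
    for r in results:
        best = r.best_module
        rows.append({
            "patient_id": r.patient_id,
            "group": r.group,
            "best_module": "+".join(best.members),
            "surge": round(best.fold_change, 3),
            "peak_index": round(best.peak_index, 3),
            "peak_time_h": best.peak_time,
            "top_markers": "+".join(r.top_markers),
        })
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "sample_results.csv", index=False)
    print(frame.to_string(index=False))
    n_hit = (frame["best_module"] == "M03+M08+M12+M19").sum()
    print(f"\nbest module equals the planted module in {n_hit}/{len(frame)} "
          "samples")


if __name__ == "__main__":
    main()
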