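# Methods

## Model and assumptions

The pipeline treats one blood draw — the cells of one patient at one
stimulation timepoint — as the replicate unit for all second-order
statistics. Per-marker standard deviations and pairwise Pearson
correlations are computed over cells after the arcsinh transform
(cofactor 5, the mass-cytometry convention) and after subsampling to a
common depth of 2000 cells, so that SD comparisons across timepoints are
not driven by unequal cell counts. This per-draw reading is the only one
under which a per-sample, per-timepoint DNB score is computable from a
single stimulation series; it assumes the cell population is homogeneous
enough that cell-to-cell covariance reflects network coupling rather than
composition shifts. Ingest therefore also supports an optional per-cluster
collapse (cluster labels are consumed, never produced), but the default —
and everything validated here — operates on a single population.

For a module **M** (≥ 2 members, ≥ 2 non-members) at one timepoint:

- `sd_in` — mean over members of the per-marker cell SD (arcsinh units);
- `pcc_in` — mean |Pearson r| over member pairs;
- `pcc_out` — mean |Pearson r| over (member, non-member) pairs;
- `I = sd_in · pcc_in / (pcc_out + ε)`, `ε = 1e-6`.

Absolute values implement sign-blind coupling; a pair involving a
zero-variance marker contributes r = 0 (with a logged count) instead of
being dropped, keeping pair-average denominators constant across
timepoints. `ε` guards the fully decoupled limit `pcc_out → 0`.

## Candidate search and ranking

Exhaustive module search is infeasible beyond ~20 markers, so candidates
come from average-linkage hierarchical clustering on the distance
1 − |r|: every dendrogram cluster of size 2–8 (capped at panel − 2), at
any cut height, at any timepoint, deduplicated. Ordering is size, then
lexicographic — fully deterministic.

Modules are ranked by the surge of `I` relative to the unstimulated
baseline, which makes scores comparable across patients with different
baseline variance:

```
surge(M) = (max_{t>0} I_M(t) + c) / (I_M(0) + c),   c = mean baseline marker SD
```

The additive ridge `c` is the index a background ("null") module attains
at baseline (`I ≈ sd̄ · r̄/r̄ = sd̄`). It is needed because for a 2-member
module `I(0)` rests on a single estimated correlation; without the ridge
the raw ratio's argmax is decided by baseline sampling noise rather than
by dynamics. `c` is independent of the candidate list (so clustering-based
and exhaustive search optimize the identical key), scales with the data
(the ranking is invariant under rescaling all markers), and leaves a
time-constant sample with every surge exactly 1, where ranking falls
through to the documented tie-breakers (larger peak `I`, then
lexicographic names). Equivalence of the clustering-based argmax with
exhaustive enumeration is asserted on 8-marker panels, where all subsets
can be scored.

A sample's top-5 dynamical markers are the best module's members ordered
by per-marker SD fold-change at the peak timepoint, extended from
next-ranked modules (same ordering, duplicates skipped) to exactly five.

## Consensus and scoring

Marker frequencies count, per marker, the samples whose top-5 contains
it; the scoring core is the 4 most frequent markers (`top_m`, m = 4), with
boundary ties broken lexicographically and logged. The alternative
`min_frequency` rule (all markers with count ≥ 5, optionally restricted to
SLE samples) is provided for the broader descriptive set. Frequencies may
be counted over all samples (default) or a group subset.

With the core fixed cohort-wide, each patient's DNB score at each
timepoint is `I(core)`; no re-ranking occurs. The prognostic parameter is
`Δ = score(2 h) − score(4 h)`. Clinical association uses Spearman rank
correlation (midranks) with an exact full-permutation p-value for n ≤ 9
pairs — cohort sizes sit at that boundary, where the large-sample
approximation is unreliable — and the asymptotic p otherwise. Prediction
is the sign rule `Δ ≥ threshold → remission-trajectory` (`≥` at the
boundary, by convention), with an optional indeterminate band; the
default threshold 0 is the natural rule for a difference, and no clinical
cutoff is asserted. "Remission/flare" here is trajectory-level
vocabulary, not a clinical claim.

## Synthetic cohort generator

Cells are drawn from a multivariate normal on the arcsinh scale (Gaussian
copula; location shift 2.0 toward nonnegative intensities) with a block
correlation structure: a planted module with per-timepoint
intra-correlation `rho_in`, module–background correlation `rho_out`, and
a uniform background `rho_bg`; member SD follows `sigma_in(t)`,
background SD is 1. Trajectories are literal per-timepoint vectors, so
the planted truth is unambiguous. Defaults (the validated study
conditions): 25 markers, module {M03, M08, M12, M19}, 2000 cells,
`rho_in = 0.05 → 0.85` peaking at 2 h, `sigma_in = 1 → 3`, `rho_bg =
0.05`, `rho_out = 0.05 → 0.02`. A uniform-block correlation matrix is
only positive semi-definite when roughly `rho_out ≤ √(rho_in · rho_bg)`,
so the module–background trajectory starts at the background level and
*falls* at the transition — a module cannot be more correlated with the
background than with itself; every implied matrix is eigenvalue-checked
at construction and any violation is rejected naming the timepoint.

Patient heterogeneity enters through a response amplitude `a ∈ [0, 1]`
that scales the `rho_in`/`sigma_in` excursions from baseline
(`x(t; a) = x(0) + a·(x(t) − x(0))`). Group ranges: HC 0.85–1.0 (nearly
uniform response), active SLE 0.10–0.45 (blunted), remission SLE
0.45–0.90. Simulated SLEDAI decreases in amplitude within each SLE group
(active > 5 ≥ remission, matching the clinical definition) and ESR is an
affine-plus-noise function of SLEDAI.

The latent per-patient `Δ` is computed by the *real* scoring machinery on
the noiseless population correlation/SD — truth is independent of
cell-sampling noise. Outcomes follow
`P(remission) = logistic(slope · (Δ − Δ₀) + N(0, noise_sd))` with
defaults slope 3, noise 0.2. The link is centred at `Δ₀`, the latent
difference of a reference patient at the active/remission amplitude
boundary (0.45): an uncentred link would saturate at probability 1 for
every patient, since latent `Δ` is strictly positive under the planted
dynamics. `slope = ∞` gives the deterministic sign rule; slope 0 the
no-information null. One global seed expands to per-(patient, slot)
substreams (`SeedSequence(seed, spawn_key=(patient_index, slot))`, slots
0–4 for timepoint draws, 100 for the clinical/outcome stream), so adding
a patient never perturbs existing draws.

What the generator does **not** emulate: raw ion counts, spillover, bead
normalization, doublets, debarcoding errors, cell-type composition shifts,
or heavy-tailed intensity noise. Passing tests therefore demonstrate that
the pipeline recovers planted second-order dynamics from realistic cell
numbers — not that real CyTOF artifacts are handled.

## Validation conditions and problem sizes

The validation harness (`dnbpipe.validation`, driven by
`scripts/acceptance.py` and the end-to-end tests) uses: 50 seeded cohorts
of 12 SLE samples (6 active, 6 remission) × 5 timepoints × 2000 cells ×
25 markers for consensus recovery, prediction accuracy (slope 3 and the
slope-0 control, both evaluated at the generator's recorded link centre
`Δ₀` as the threshold) and the severity-correlation sign; 20 fixtures of
8 markers × 5000 cells for exhaustive-search agreement; a 12-point grid
and three scale factors for the composite-index laws. Derived seeds are
spread with a fixed multiplier so the harness arms draw disjoint streams.

## Numerical choices and degenerate inputs

- Correlations from `numpy.corrcoef`; non-finite entries (zero variance)
  set to 0 and counted.
- PSD tolerance 1e-8 on the smallest eigenvalue; Cholesky falls back to a
  1e-10 diagonal jitter for semi-definite (singular) specifications.
- Subsampling below 50 cells is refused; second-order statistics at that
  depth would be noise.
- An all-constant panel yields an empty candidate list with a warning,
  not an error; a missing stimulation timepoint is a hard error (no
  imputation), because `Δ` needs 2 h and 4 h and ranking needs all five.
- FCS support is a minimal list-mode float reader (3.0/3.1, `$PnS` names
  falling back to `$PnN`), plus a writer used to fabricate round-trip
  fixtures at test time.

## Known limitations

- The module search is heuristic; equivalence to exhaustive search is
  established on small panels only.
- The prediction threshold is scenario-dependent; with no printed
  clinical cutoff to reproduce, accuracy is assessed at the generator's
  known link centre, which real data would not provide (a practitioner
  would calibrate on follow-up outcomes, e.g. via
  `scoring.truth_optimal_threshold`).
- Per-cluster median collapse is available but unvalidated against the
  per-cell default.
- Spearman p-values for 5 ≤ n ≤ 9 are exact conditional on the observed
  midranks; confidence intervals for rho are not provided.
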