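# dnbpipe

Dynamic network biomarker (DNB) analysis of stimulation time-course
cytometry data, built around the question of predicting disease flares and
remission in systemic lupus erythematosus (SLE) from the way a patient's
immune network responds to a short IL-2 stimulation.

## The problem and the method

Static biomarkers separate sick from healthy, but say little about whether
a patient's current state is *stable*. DNB theory holds that as a system
approaches a critical transition, a small group of molecules starts to
fluctuate together: their standard deviations rise, their mutual
correlations tighten, and their correlation with the rest of the network
drops. For a candidate module **M** of markers measured across single
cells at one timepoint, the three conditions fold into a composite index

```
I(M) = sd_in(M) · pcc_in(M) / (pcc_out(M) + ε)
```

where `sd_in` is the mean member standard deviation (arcsinh scale),
`pcc_in` the mean absolute pairwise Pearson correlation inside the module,
`pcc_out` the mean absolute correlation between members and non-members,
and `ε = 1e-6`.

The pipeline takes per-patient PBMC expression matrices (cells × markers)
at IL-2 stimulation timepoints {0, 0.5, 1, 2, 4} h and:

1. **ingest** — reads FCS 3.0/3.1 or delimited tables, applies the
   arcsinh transform (cofactor 5), subsamples to a common cell depth;
2. **module search** — finds candidate modules per sample by
   average-linkage clustering on 1 − |r|, scores `I` at every timepoint,
   and ranks modules by the regularized surge of `I` over the
   unstimulated baseline;
3. **consensus** — pools each sample's top-5 dynamical markers and fixes
   the 4 most frequent as the cohort's scoring core;
4. **scoring** — computes each patient's DNB score trajectory on that
   fixed core; the prognostic parameter is `Δ = score(2 h) − score(4 h)`.
   A large Δ (a sharp surge that recedes) marks a responsive network; Δ
   correlates negatively with disease activity (SLEDAI, ESR), and
   thresholding Δ predicts remission- vs flare-bound trajectories.

Because the underlying clinical CyTOF data are not publicly deposited,
validation is end-to-end on a synthetic cohort generator that plants the
DNB signature — a marker module whose intra-correlation climbs from 0.05
to 0.85 at 2 h while member SD triples and module–background correlation
decouples — with per-patient response amplitudes that drive both simulated
severity and remission/flare outcomes.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_rank_modules.py
python analysis/03_consensus_core.py
python analysis/04_score_and_predict.py
```

simulates 16 patients (4 HC, 6 active SLE, 6 remission SLE; planted module
M03+M08+M12+M19, seed 42), re-ingests them from disk, and prints:

```
top-4 scoring core: M03, M12, M19, M08

group mean trajectories:
       score_0h  score_0.5h  score_1h  score_2h  score_4h
HC         0.98        7.07     28.83     96.75     10.51
aSLE       1.01        2.34      4.40      7.95      2.54
rSLE       0.92        4.67     14.37     36.12      5.91

Spearman rho(delta, SLEDAI) = -0.961 (p = 3.1e-09)
Spearman rho(delta, ESR)    = -0.909 (p = 1.1e-06)
remission/flare prediction accuracy: 0.92 on 12 SLE patients
```

The consensus core is exactly the planted module; active SLE shows the
flattest stimulation response (smallest score excursion); the 2h−4h score
difference tracks severity negatively and separates remission from flare
outcomes. Per-patient tables land under `results/`.

The same steps run from a shell via the `dnb` command
(`dnb simulate | run | consensus | score`).

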