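# Methods

`reverie` implements a group-level analysis of music-evoked memory
reactivation during naturalistic movie viewing, together with a synthetic
data generator that plants the effects the analysis is designed to detect.
This note documents the model, the estimators, the numerical choices, and
what the synthetic data do and do not establish.

## The measurement problem

Two groups watch the same film; one hears the original soundtrack, in
which a handful of musical themes recur, and the other hears a version
with the music removed.  When a theme recurs, it can act as a retrieval
cue for the earlier scenes it accompanied.  The analysis asks whether the
neural reinstatement of those earlier scenes — measured as spatial pattern
similarity in parcellated BOLD data — predicts whether the earlier scenes
are recalled the next day.

The central difficulty is that two scenes sharing a song also share sound:
within-group pattern similarity between them could reflect hearing the
same music rather than remembering the earlier scene.  The design solves
this by comparing *across* groups: a music participant's pattern during a
later scene is correlated with the **no-music** group's average pattern
for the earlier scene.  Any shared signal must then reflect non-musical
scene content.

## Reactivation scoring

For each repeated song, consecutive same-song scenes are collapsed into a
*mega-scene* (unweighted mean of the member scenes' time-averaged
patterns).  Each mega-scene is paired with every strictly-earlier same-song
scene — "strictly earlier" meaning the earlier scene's index precedes the
mega-scene's first member, so nothing inside the run is ever compared with
itself (such comparisons could reflect working memory rather than
retrieval).  Per pair, participant and parcel:

- **raw** = Pearson correlation (across voxels) of the subject's
  mega-scene pattern with the comparison group's average earlier-scene
  pattern;
- **baseline** = the same computed within the comparison group by
  leave-one-out (each held-out comparison participant's mega-scene against
  the remaining participants' average), averaged over held-out
  participants.  This removes ordinary between-scene similarity;
- **contrast** = raw − baseline;
- **reactivation score** = the contrast z-scored against a permutation
  null: the earlier-scene identity of each pair is reassigned by a random
  permutation of the full repeated-music scene pool, and the *same*
  permutation is applied inside both the raw and the baseline term so the
  null respects the contrast's structure.  z = (true − mean(null)) /
  sd(null), with the sample (ddof = 1) standard deviation.

Pair-level z values are averaged per earlier scene (a scene cued by
several later mega-scenes contributes its unweighted mean, with `n_pairs`
recorded).  Design choices worth flagging:

- the permutation unit is the earlier-scene *assignment*, drawn from all
  repeated-music scenes, per participant and parcel; shuffle substreams
  are derived deterministically from one master seed via
  `SeedSequence(seed, spawn_key=(parcel, participant))`, so serial and
  parallel runs agree and a brute-force re-implementation can reproduce
  the exact null draws;
- correlations are not Fisher-transformed before subtraction; the only
  normalization is the permutation z itself;
- TR membership of a scene uses the TR-onset-in-half-open-interval rule
  `[start + lag, end + lag)`; the default lag is 0 s (no hemodynamic
  shift is applied; `lag_s` is exposed for users who want one).

The no-music control runs the identical machinery within the no-music
group: each held-out participant plays the subject role against the
remaining participants, and is excluded from both the comparison average
and the baseline computation.  This requires at least 4 participants
(subject + a leave-one-out average over ≥ 2 of the ≥ 3 remaining).

## Subsequent-memory statistics

Per participant, scene-level scores are split into subsequently-remembered
and subsequently-forgotten bins and averaged within bins; the binned means
are compared with a one-tailed t-test (remembered > forgotten).  The test
is **paired** by default — the bins are within-participant means — with an
independent-samples variant exposed for sensitivity analyses.
Participants with an empty bin are dropped listwise for that parcel (a
paired difference is undefined) and the drop is logged.  Per-parcel
p-values are corrected by Benjamini–Hochberg FDR within a stated
correction set (by default the Default-network parcels, mirroring an
a-priori hypothesis about where event content lives), with significance
reported at q ≤ 0.1.  Degenerate cases are flagged rather than silently
propagated: all-zero differences give (t = 0, p = 0.5); non-zero constant
differences give ±inf with a `degenerate` flag.

## Encoding-strength control

A remembered-vs-forgotten difference in reactivation could arise with no
retrieval process at all if well-encoded scenes are both reinstated more
strongly and recalled better.  Spatial intersubject correlation (ISC) —
the correlation between one participant's time-averaged scene pattern and
the mean pattern of the other N−1 participants, computed within condition
— serves as a per-scene proxy of encoding strength: attentive encoding
pulls a participant toward the group-typical pattern.

The control proceeds in three steps: (1) run the same binned
subsequent-memory test on ISC and select the parcels where ISC predicts
recall at a liberal uncorrected p < 0.05 (erring toward removing more
encoding variance); (2) within each participant, sequentially regress the
selected parcels' ISC scene-vectors out of each target parcel's
reactivation scene-vector — one ordinary-least-squares step per region,
intercept included, residuals carried forward; (3) re-run the
subsequent-memory statistics on the final residuals.  The sequential
(rather than joint) regression follows the screening-then-removal recipe
this analysis replicates; it is order-dependent for correlated predictors,
so the region order is fixed (ascending parcel id) and recorded.  Constant
predictors are skipped with a warning.  After each step the residuals are
exactly orthogonal to that step's predictor-with-intercept; with mutually
orthogonal centered predictors the result equals joint multiple
regression.

## Condition contrasts

Per-condition subsequent-memory t statistics are converted to z-scores by
tail-probability matching through the standard normal (not the crude
z = t, which is biased at the modest per-condition degrees of freedom).
Three contrasts are provided:

1. **parcel-wise** — one-tailed paired t (music > no-music) on the
   per-parcel z difference across an a-priori parcel set, df = parcels − 1.
   This treats participants as a fixed effect and cannot generalize to new
   participants; the caveat travels in the result dict.
2. **participant-wise** — per participant, the across-parcel reliability
   of the remembered-vs-forgotten difference (paired t across parcels →
   z), then a one-tailed two-sample t between groups, df = n₁ + n₂ − 2.
3. **network-wise** — contrast 1 within each of 9 bilateral networks
   obtained by collapsing 17-network-style labels (strip the trailing
   A/B/C subnetwork letter; keep central and peripheral visual networks
   distinct), BH-FDR over the 9 network p-values.  Networks with fewer
   than 3 parcels are skipped with a warning.

## Consensus scene boundaries

Scene boundaries come from pooled rater annotations: every boundary
contributes a unit-mass Gaussian (default σ = 3 s) to a density evaluated
on a regular grid (default 0.1 s); candidate boundaries are the local
maxima of that density, and those whose height reaches the chosen
percentile (default 90th) of the candidate-peak heights are kept.
Thresholding on peak heights, rather than on the percentile of all grid
density values, is deliberate: with sparse boundaries most grid points
carry near-zero density, so a grid-value percentile threshold is
vanishingly small and a single stray rater's boundary would always
survive; the peak-height percentile keeps only boundaries with genuine
multi-rater support.  A primary rater's finer segmentation is then
reconciled with the consensus: an internal boundary is kept iff a
consensus boundary lies within `snap_tolerance_s` (default 3 s) of it,
otherwise the flanking scenes merge (merged scenes keep their song label
only when all members agree).

## Synthetic data generator

Each scene `s` in each parcel `k` has a fixed unit-norm spatial signature
`u_{k,s}` shared by all participants and both groups.  Participant `p`'s
signal during scene `s` is `e_{p,s} · g · u_{k,s}` plus i.i.d. Gaussian
voxel noise, where `g` is the signature gain (default 1) and
`e_{p,s} = exp(encoding_sd · N(0,1))` is a lognormal per-participant,
per-scene encoding strength (default spread 0.5), shared across parcels
(a global attention fluctuation).  In the music group only, scenes of a
later occurrence block additionally carry the mean of the strictly-earlier
same-song scenes' signatures, each weighted by a planted reactivation
amplitude

    gamma_{p,s'} = react_gain · e_{p,s'}^kappa · exp(react_sd · eta_{p,s'}),

restricted to the configured affected parcels.  The coupling exponent
`kappa` (default 1) ties reinstatement to encoding strength — well-encoded
scenes are reactivated more strongly — which is precisely the confound the
ISC control exists to remove; `eta ~ N(0,1)` is the encoding-independent
retrieval latent.  Recall is Bernoulli with

    logit P(remembered) = a + b · e_tilde + c · eta,

where `e_tilde = log(e)/encoding_sd` is the standardized encoding latent
and the `c · eta` term applies only to cued scenes of music participants
when reactivation is planted at all.  Setting `react_gain = 0` makes the
two groups draws from one generative process (exchangeable); `c = 0` makes
recall depend on encoding alone, the pure-confound condition.

Defaults mirror the emulated study where it states them: 24 participants
per group, TR 1.5 s, and a bundled 407-scene annotation table with 6
repeated songs covering 93 scenes (per-song counts 4/10/12/18/22/27, mean
15.5; the "Phone Call" song's later block spans scenes 111–115 with all
earlier occurrences before scene 111; 67 strictly-earlier cue pairs in
total).  Parcel count (4) and voxels per parcel (30) are artifact sizes
with no empirical referent, chosen small.  The default
`react_gain = 0.95` is calibrated so that, under the standard test
conditions below, the planted pair-level raw-correlation uplift in
affected parcels is ≈ 0.15; `react_sd = 0.5` and the recall coefficients
(a = 0, b = 1, c = 2) give recall rates near 50% with a strong but not
deterministic dependence on the latents.

What the generator does *not* emulate: hemodynamic convolution (patterns
are consumed time-averaged, so a boxcar-at-TR model is sufficient and
keeps closed-form oracles possible), spatial autocorrelation within and
between parcels, motion/physiological artifacts, scanner drift, and any
topographic realism in the parcel layout.  Passing tests therefore
establish the *statistical* correctness and calibration of the estimators
under the assumed generative structure, not robustness to real fMRI
artifacts.

## Problem sizes used in the test suite and acceptance script

Simulation-based checks run on scaled-down scene tables chosen so the
whole suite completes at desk scale:

- *null calibration*: 3 songs × two 4-scene occurrence blocks (12 cue
  pairs, 24-scene pool, scenes 4.5 s at TR 1.5 s), 24 participants/group,
  24 voxels/parcel, 500 parcels in 10 independent datasets, 200
  permutations;
- *baseline correction*: same table, 8–16 replicate datasets of 8 parcels;
  replicate datasets are the independent units for the standard error
  (within one dataset, the fixed scene signatures induce a shared offset
  across participants, so participant-level standard errors would be
  anticonservative);
- *parameter recovery*: same table, 50 parcels with 5 affected, 30–50
  replicates;
- *ISC control*: 8 songs × two 4-scene blocks (32 scored scenes), 15
  parcels with 5 affected — sized so the screened-region count stays well
  below the scored-scene count, as in the replicated design (20 regions
  against ~60 scored scenes); with as many screened regions as scenes the
  sequential regression would remove everything by overfitting.

## Known limitations

- The permutation unit ("shuffling event patterns") and the pair→scene
  aggregation rule are interpretive choices; both are logged once per run.
- Sequential residualization is order-dependent for correlated
  predictors; the fixed ascending-id order is recorded, and a seeded
  random order is available for sensitivity checks.
- The parcel-wise condition contrast licenses conclusions about parcels,
  not participants; the participant-wise variant exists for that reason.
- ISC is a proxy of encoding strength, not a measurement of it; the
  generator's `kappa` makes the proxy's target explicit, but with real
  data the residual analysis can only rule out the variance ISC captures.
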