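# reverie

Music-evoked memory reactivation analysis for naturalistic movie-watching
fMRI.

## The problem

When a film repeats a musical theme, the theme can act as a retrieval cue
for the earlier scenes it accompanied.  `reverie` measures that cue-evoked
reinstatement in parcellated BOLD data and asks whether it predicts
next-day recall of the earlier scenes.  It is written for researchers
analyzing two-group naturalistic designs — one group hears the original
soundtrack, a control group watches a music-free version — and for anyone
who wants a fully synthetic, ground-truth-planted testbed for
reinstatement statistics.

The core quantity is the **reactivation score** for a cue pair: a later
mega-scene *M* (a run of consecutive scenes sharing song *g*) and a
strictly-earlier scene *s* with the same song.  For music participant *p*
and parcel *k*,

    raw(p, k, M, s)   = corr( pattern_p(M),  mean over no-music group of pattern(s) )
    base(k, M, s)     = mean_q corr( pattern_q(M), mean over no-music group \ q of pattern(s) )
    contrast          = raw − base
    z(p, k, M, s)     = ( contrast − mean(null) ) / sd(null)

where patterns are voxelwise time-averages over scene TRs and the null
re-assigns each pair's earlier scene by a random permutation of the
repeated-music scene pool (the same shuffle inside the raw and baseline
terms).  Comparing *across* groups guarantees the similarity cannot be
driven by hearing the same music.  Scene-level scores are then binned by
subsequent recall (remembered vs forgotten), tested per parcel with a
one-tailed paired t-test, and FDR-corrected.  The package also provides
the spatial-ISC encoding-strength control (screen, sequential
residualization, re-test), the within-group no-music control, and three
music vs no-music condition contrasts.  See `docs/methods.md` for the full
model and its assumptions.

## Worked example

Plant reactivation in 2 of 8 parcels of a small synthetic dataset
(24 participants per group, 3 repeated songs), score it, and test the
remembered-vs-forgotten difference:

```python
from reverie import SimConfig, generate, music_reactivation, searchlight_memory
from reverie.annotations import compact_scene_table

ds = generate(SimConfig(n_participants=24, n_parcels=8, voxels_per_parcel=24,
                        scene_table=compact_scene_table(),
                        affected_parcels=(0, 1), seed=1))
scores = music_reactivation(ds.data["music"], ds.data["nomusic"], ds.scenes,
                            ds.tr_s, n_perm=1000, seed=1,
                            music_ids=ds.participant_ids["music"])
effects = searchlight_memory(scores, ds.recall_for_group("music"),
                             correction_parcels=range(8))
print(effects[["parcel_id", "t", "p", "q", "significant"]].round(3).to_string(index=False))
```

```
 parcel_id      t     p     q  significant
         0  3.909 0.000 0.003         True
         1  2.620 0.008 0.031         True
         2 -0.385 0.648 0.741        False
         3  0.660 0.258 0.447        False
         4 -0.693 0.752 0.752        False
         5 -0.083 0.533 0.710        False
         6  0.594 0.279 0.447        False
         7  1.231 0.115 0.308        False
```

The two parcels carrying planted reactivation (0 and 1) show remembered >
forgotten reactivation scores (one-tailed paired t over 24 participants)
and survive BH-FDR at q ≤ 0.1; the six null parcels do not.  `scores` is a
long table with one permutation-z reactivation score per (participant,
parcel, earlier scene), plus the raw and baseline-corrected correlations
it was built from.

The same pipeline runs end to end from the shell:

```bash
reverie simulate --out demo-data --compact --seed 1
reverie run --config demo.yaml        # reactivation → memory → ISC control → contrasts
reverie react --data demo-data --out scores.tsv --n-perm 1000 --seed 1
```

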