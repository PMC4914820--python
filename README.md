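# songrhythm

Durational-contrast analysis of monophonic songs: does the rhythm of a
culture's children's songs reflect — or exaggerate — the rhythm of its
language?

Stress-timed languages (English) show high durational contrast between
successive vocalic intervals; syllable-timed languages (French) show low
contrast. The same contrast measure applies to the note durations of a
melody, which makes it possible to ask whether songs originally set to
English or French lyrics inherit their language's rhythm, whether
children's songs differ from folk songs, and whether listeners use rhythm
when judging a song to be "for children". `songrhythm` implements that
whole pipeline for quantitative musicologists and music-cognition
researchers: symbolic score I/O, the rhythm statistic, group contrasts,
listener-rating regressions, and a synthetic corpus/panel generator so
every stage is testable without access to a hand-entered corpus.

## The statistic

The normalized pairwise variability index of a duration sequence
d₁ … d_m is

    nPVI = 100/(m−1) · Σ_{k=1}^{m−1} |d_k − d_{k+1}| / ((d_k + d_{k+1})/2)

It is 0 for perfect isochrony and approaches (never reaches) 200 as the
contrast within a pair grows without bound; it is invariant to tempo
(global rescaling of durations). At the song level, songs are
phrase-segmented and **pairs that straddle a phrase boundary are
excluded**: only within-phrase adjacent pairs enter the statistic.
Group contrasts are pooled two-sample t-tests, computable directly from
group summaries (n, mean, SEM). Listener panels are analyzed by
regressing each group's per-song "for children" endorsement proportion
on four song-level predictors — mean familiarity, mean liking, tempo
(mean note duration in ms) and nPVI — reporting each predictor's simple
correlation *r* and its **R² change**, the drop in the full model's R²
when that predictor alone is removed.

## Worked example

Simulate a study-scale corpus (269 songs in four language × song-type
cells) with a 140-listener rating panel, then run the full analysis:

```sh
songrhythm simulate --seed 42 --out demo
songrhythm npvi demo/corpus.csv --out demo/npvi.csv
songrhythm compare demo/npvi.csv --out demo/report.json
songrhythm ratings demo/ratings.csv demo/npvi.csv --out demo/regression.json
```

which prints (among other logging):

```
INFO songrhythm: songs read: 269; undefined nPVI: 0; boundary pairs excluded: 629
INFO songrhythm: children: t(127) = 1.664, p = 0.0986
INFO songrhythm: folk: t(138) = 0.407, p = 0.6847
group                 predictor            r   R2 change
monolingual_american  familiarity      0.256      0.0033
monolingual_american  tempo           -0.947      0.8266
monolingual_american  npvi            -0.221      0.0003
...
french                npvi            -0.617      0.1559
french                (full model)                0.9033
```

Reading this: 629 phrase-junction pairs were excluded from the nPVI
computations. The children's-song contrast (English vs French) at this
seed is positive but not significant — with the generator's default
between-song dispersion (back-computed from published standard errors)
the power of this design is only ≈ 0.57, so a significant children's
contrast appears in roughly half of the seeds. In the regression block,
the French-like listener group shows the expected negative nPVI loading
(*r* = −0.62, unique R² change 0.16): songs with lower durational
contrast are endorsed as "for children" by raters whose endorsement
model penalizes contrast, while the monolingual group's nPVI
contribution is essentially nil.

The same operations are available as a library — see
`songrhythm.npvi_song`, `songrhythm.compare_report`,
`songrhythm.regress_child_directedness`,
`songrhythm.generate_corpus` / `generate_ratings`.

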