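# Methods

## The rhythm statistic

For a sequence of durations d₁ … d_m the normalized pairwise variability
index is the mean over adjacent pairs of 100·|d_k − d_{k+1}| / ((d_k +
d_{k+1})/2). Properties relied on throughout the package:

- **Range.** Each pair contrast lies in [0, 200); the value 200 is a
  supremum, attained only in the limit of an infinite duration ratio.
  A two-element series with ratio 10⁹ evaluates to 199.9999996.
- **Scale invariance.** nPVI(c·d) = nPVI(d) for any c > 0, so beats,
  milliseconds, and the generator's measure-filling rescaling all give
  identical values.
- **Order sensitivity.** Unlike a dispersion measure, the statistic
  depends on ordering: [1,2,1,2] scores 66.67 while [1,1,2,2] scores
  22.22.
- **Undefined ≠ zero.** A sequence with fewer than two elements has no
  pairs; the package signals this (`NoPairsError`) rather than
  returning 0.

### Elements and preprocessing

Scores carry exact rational durations (quarter note = 1); floats appear
only inside the statistic, where contrasts are computed in double
precision. An *element* is, by default, a notated note duration after
tie chains are merged (summed) and grace notes dropped; rests are
discarded. An alternative *inter-onset* policy defines the element as
the interval to the next element's onset, so rest time (and dropped
grace-note time) accrues to the preceding note; the last element of a
phrase keeps its span to the phrase end. Both policies are exposed
because notated-duration and inter-onset readings of a melody differ
exactly where notes are followed by rests; the default is notated
duration. Phrases emptied by preprocessing are dropped with a warning.

### Aggregation across phrases

Pairs straddling phrase boundaries are excluded. Two aggregations are
offered: `pooled_pairs` (default) averages all surviving pair contrasts
pooled across phrases — equivalent to computing the whole-song statistic
and simply omitting the junction pairs — and `phrase_mean` averages
per-phrase nPVIs with equal phrase weight. They coincide for single-
phrase songs and for equal phrase lengths. Phrases contributing a single
element are skipped (logged), and a song where no phrase contributes a
pair raises an explicit undefined-statistic error; batch tables turn
that into a NaN row plus a warning so one degenerate song cannot abort a
corpus run.

## Tempo

The tempo measure is the mean element duration in milliseconds. Beats
convert to ms via the song's notated tempo when present, otherwise a
default of 100 bpm (600 ms per quarter note) — the same rule used when
rendering stimuli to MIDI. Rendering fixes 480 ticks per quarter,
writes phrase starts as marker meta events named `phrase`, and can
transpose to C major (configurably down, e.g. G → −7 semitones, or up,
G → +5). MIDI reading accepts any positive tick resolution, rejects
polyphonic overlap, and recovers phrase structure either from `phrase`
markers or from silences of ≥ 2 beats (configurable), since plain MIDI
carries no phrase marks.

## Group comparisons

Group summaries are n, mean, SD (n−1 denominator) and SEM = SD/√n.
Two-sample tests work from summaries alone, which allows exact
recomputation of published contrasts from printed means/SEMs/ns; the
default is the pooled-variance two-tailed form (the printed degrees of
freedom equal n₁+n₂−2, and the published children's-song p is the
two-tailed one), with Welch and one-tailed variants available — the
published folk-song p of 0.10 at t(138) = 1.27 is only consistent with
a one-tailed reading, so tailedness is caller-selectable. No
multiple-testing correction is applied at the corpus stage. Per-language
corpus means are n-weighted means of the cell means.

## Ratings regression

Per listener group, per song: mean familiarity, mean liking, and the
endorsement proportion ("for children"). The group's proportions are
regressed by OLS on familiarity, liking, tempo and nPVI, entered raw —
R², simple r, and R² change are invariant to affine predictor rescaling,
so standardization is immaterial to the reported quantities. R² change
for predictor x is R²(full) − R²(without x), computed by refitting the
four leave-one-out submodels, with the one-degree nested F-test for
significance. Rows with missing values are dropped listwise per group;
rank-deficient designs are rejected with the collinear predictors named.
Confidence ratings are ingested and stored but enter no analysis.
Familiarity and preference predictors are the same group's means as the
response being modeled (not all-listener means).

## Synthetic data

The generator exists because the analyzed corpus and rating data are
not redistributable; it emulates their published summary structure so
the pipeline can be exercised end to end.

**Corpus.** Four cells (language × song type) with defaults taken from
the published design: ns 68/61/72/68, mean nPVI targets 40.43 (English
children's), 33.80 (French children's), 43.60 (English folk), 40.10
(French folk). Published dispersions are SEMs; the generator's
between-song SD defaults to SEM·√n (15.7–17.7) — an approximation, since
the true SDs are not printed. Each song draws a target v ~ N(target,
SD), clamped to [0, 199]. Contrast is injected by long–short
alternation, the musical analogue of vowel reduction: a strictly
alternating series r, 1, r, 1, … with r = (200+c)/(200−c) has nPVI
exactly c. Successive elements flip between the long and short state
with probability `alternation_prob` (default 0.85, so rhythms are not
rigidly alternating) and otherwise repeat; a flipped pair contributes
contrast c, a repeated pair 0, so with c = v/alternation_prob the
expected pooled song nPVI is exactly v, and `expected_npvi` returns this
closed form per cell. The drawn v is quantized to 1/1000 so r is an
exact rational and durations stay exact. Meters are drawn from the
published per-language marginals (the French counts cover 121 of 129
songs; the marginal is renormalized); phrase counts default to 2–5,
phrase lengths to 8–16 elements, and each phrase is rescaled — a no-op
for the statistic — to fill a whole number of measures. Base note values
vary per song (sixteenth- to quarter-note short units), which gives
between-song tempo variance of roughly the published magnitude (SD ≈
210 ms) and keeps tempo from being a pure function of nPVI. Pitches are
a C-major placeholder; melodic realism is out of scope.

**Panels.** Three listener groups (70 monolingual American, 30
bilingual American, 40 French); every participant rates every song (the
published list-splitting into 5 × 54 is not modeled — it only thins
per-song rater counts). Familiarity is a clamped integer around a base
of 2.6 with an own-culture bonus (+1.3), a children's-song bonus (+0.7)
and N(0, 1.2) noise; liking tracks familiarity (slope 0.6) with its own
noise. Endorsement is Bernoulli(logistic(β₀ + β₁·familiarity +
β₂·tempo + β₃·nPVI)) with defaults β₁ = +0.5 and β₂ = −0.006/ms for all
groups and β₃ = 0, −0.02, −0.05 for monolingual, bilingual and French
groups — the published sign structure (familiarity positive, tempo
negative everywhere, nPVI negative only for syllable-timed-language
listeners, weakly for bilinguals). Intercepts center endorsement near
0.5. The model is calibrated to signs, not to the published effect
magnitudes: in generated panels tempo carries more unique variance than
in the real data, because synthetic tempo is noiseless at the song
level. Passing recovery tests therefore shows the pipeline recovers a
known generating process, not that real listeners behave this way.

**Determinism.** All randomness flows from one integer seed through one
`numpy` Generator; serialized outputs are byte-identical across runs
with the same seed and config.

## Validation choices and known limits

- The vectorized statistic is checked to 1e-12 against a naive
  double-loop reference on 1,000 random series, and scale invariance to
  1e-12 under a ×600 rescaling.
- The generator's analytic expectation is checked against the empirical
  mean of 5,000 simulated songs within 3 Monte-Carlo standard errors;
  recovery suites use 100 corpus replicates (two cells of 60 songs) and
  200 panel replicates on one default corpus, sizes at which the whole
  suite runs in well under a minute for the stochastic parts.
- Power of the published children's-song design: with targets 40.43 vs
  33.8 and SD = SEM·√n at n = 60/cell, the pooled t has noncentrality
  ≈ 2.18 and two-tailed power ≈ 0.57 at α = 0.05. Replicate runs of the
  generator reproduce that rate; a significant contrast in nearly every
  replicate is not achievable under these dispersions, and the test
  suite records this as an expected shortfall rather than relaxing the
  generator.
- Degenerate inputs: zero within-group variance with equal means yields
  t = 0; with unequal means it raises (infinite t) rather than
  returning a number. Zero-variance correlation inputs raise. Ties into
  rests break the tie chain. Transposition folds out-of-range pitches
  by octaves.
- Out of scope: MusicXML/ABC parsing, audio rendering, polyphony,
  mixed-design ANOVA/ANCOVA machinery, and melodic/lyrical realism in
  the generator.
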