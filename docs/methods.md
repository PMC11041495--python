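# Methods

This note records the models, parameter choices and numerical decisions
behind `voicerisk`, in the package's own terms.

## Threat model

The attack simulated throughout is a marketer attack: the adversary tries to
reidentify as many records as possible in a shared, de-identified data set by
linking them to an identified reference collection.  One attack instance is a
*speaker split*: a known set (the adversary enrolls every eligible recording
per speaker), an unknown set with exactly one probe recording per speaker,
and an overlap subset of unknown speakers who also appear in the known set —
the only probes for which a correct match exists.  For overlap speakers the
probe recording is withheld from that speaker's enrollment average, since the
shared recording would not also sit in the adversary's collection.  The
adversary is assumed not to know the overlap size (acceptance variant
`"all"`); `"rank1"` and `"topN"` model better-informed adversaries.

## Embedding model and synthetic cohorts

Real pipelines embed each recording as a fixed-length x-vector.  The
generator reproduces the statistical structure such embeddings are known to
have, rather than the audio:

    x = R(θ_t) y_s + b_t + ε,   y_s ~ N(0, Φ_b),   ε ~ N(0, σ_t² Φ_w + c² I)

* `y_s` — speaker identity latent, between-speaker covariance `Φ_b`
  (isotropic or full, PSD).
* `R(θ_t)` — rotation by the task angle θ_t ∈ [0, π/2] applied in ⌊d/2⌋
  orthogonal 2-planes drawn once from the seed.  The expected cosine between
  a latent and its rotated image is cos θ_t, so θ_t directly controls
  cross-task similarity while leaving within-task geometry intact.  (A
  rotation confined to a single 2-plane would touch only 2/d of the latent
  energy and cannot attenuate high-dimensional embeddings appreciably.)
* `σ_t` — per-task within-speaker scale; stereotyped tasks (sustained
  vowels, syllable repetitions) have fewer dynamic speaker factors and hence
  smaller σ_t.
* `b_t` — small task-specific mean offset; `c` — isotropic
  recording-condition noise.  Recording-condition variation is modelled by
  this single term only; medium, microphone distance and disorder severity
  are not modelled separately.

The *mayo-like* task preset places six elicited tasks on the connectedness
ordering (reading > sentence > word > SMR > AMR > vowel) with θ_t rising
(0.08, 0, 0.25, 0.45, 0.65, 0.90 rad) and σ_t falling (1.05, 1.0, 0.9, 0.75,
0.6, 0.45), sentence repetition being the reference.  These values were
chosen once so that the two mechanisms produce the qualitative pattern
clinical speech shows: tasks far from connected speech are poor cross-task
probes but strong within-task probes.

The random stream is consumed in a fixed order (rotation basis, task
offsets, speaker latents, per-task noise), so identical (config, seed) pairs
are bit-identical and cohorts that differ only in angles share latents and
noise.

**Operating point.**  The experiment presets use dim 16, unit between-speaker
variance and within-speaker variance 0.5 (`GeneratorConfig` itself defaults
to dim 192, matching real x-vectors).  At that setting the fitted verifier
runs at a single-trial equal error rate of ≈1.5%, inside the 1–3% band
reported for x-vector/PLDA systems on web-quality speech.  Under the strict
calibration this recovers roughly 40% of genuine matches while the
false-accept rate sits near the extreme-value tail of the calibration
subsets (≈5×10⁻⁵), so false-accept counts grow roughly linearly over
desk-scale search spaces (10⁴–10⁵ comparisons) — the same regime the
full-scale phenomenon occupies at 10⁵–10⁶ comparisons with a stronger
embedder.

**What passing tests do and do not show.**  The generator emulates
second-order structure, task mismatch and seed-reproducibility.  It does not
emulate heavy-tailed or non-Gaussian embedding geometry, speaker-dependent
recording counts, disorder-driven within-speaker drift over years, content
overlap between tasks, or annotation errors.  Results on synthetic cohorts
therefore validate the *machinery* and reproduce *qualitative orderings*;
they are not estimates of absolute risk for any real data set.

## PLDA verifier

Full-rank two-covariance PLDA, fitted by EM with the global mean fixed at
the arithmetic mean of the training embeddings.  The per-speaker marginal
likelihood factorises through an orthonormal change of variables into a
speaker-mean term `N(x̄; μ, Φ_b + Φ_w/n)` plus `n−1` deviation terms
`N(·; 0, Φ_w)`, which is how the log-likelihood is evaluated exactly.
Details:

* Initialisation: one-way ANOVA moment estimates (deterministic); `Φ_b`
  eigenvalues floored slightly above zero because the zero matrix is an EM
  fixed point.
* Regularisation: `λI` with `λ = 10⁻⁶ ×` mean diagonal is added to a
  covariance whose smallest eigenvalue is not safely positive; the event is
  logged and flagged on the model.
* Convergence: stop when the log-likelihood gain falls below `tol`
  (absolute; default 10⁻³) or at `max_iter`.  The per-iteration
  log-likelihood is recorded and must be non-decreasing to 10⁻⁸ slack.
* Training uses per-recording embeddings (one averaged vector per speaker
  would make `Φ_w` unidentifiable); speaker averaging happens at enrollment,
  with the enrolled vector's within-covariance divided by the number of
  averaged recordings during scoring — the standard treatment of
  multi-session enrollment.
* Scoring uses the conditional decomposition
  `LLR = log N(p | e, same) − log N(p)`, vectorised per distinct averaging
  count; it agrees with brute-force stacked joint-Gaussian evaluation to
  10⁻⁸ (tested), and no inverse of `Φ_b` is ever taken, so a singular
  between-covariance is legal (`Φ_b = 0` gives LLR ≡ 0).
* Optional preprocessing (global centering, length normalisation) is
  deliberately absent: the generator produces embeddings already in the
  model family, and the scorer is exact there.

## Threshold calibration

The detection cost `C_FR·FR·π + C_FA·FA·(1−π)` is evaluated in *rates* mode
by default (miss rate and false-accept rate), matching standard minDCF
implementations; a *counts* mode using raw counts is available for literal
fidelity to cost-function prose.  `min_dcf_threshold` searches the midpoints
of adjacent sorted unique scores plus ±∞ sentinels and breaks cost ties
toward the largest (most conservative) threshold; it matches a 10⁴-point
exhaustive grid on every toy tried.  The equal-error-rate alternative
minimises |FAR − FRR| over the same candidates and reports (FAR+FRR)/2.

The bootstrap protocol: per run, two subsets of `subset_size` speakers
(default 100) are drawn independently from the training cohort — so they may
overlap — subset A is enrolled by speaker averaging, one held probe
recording is drawn per subset-B speaker (withheld from A's average when the
speaker has another recording), all A×B pairs are scored, and the run's
minDCF threshold is taken.  Runs whose subsets share no speaker contain no
genuine trial and are discarded; the final threshold is the mean over
retained runs (default 200 runs, optional early stop when the running mean
moves < 10⁻³ over 25 retained runs).

Within a bootstrap run the candidate set is restricted to the finite
midpoints.  With strict costs in rates mode, rejecting everything costs
`C_FR·π = 10⁻⁴` while a single false accept among ~10⁴ impostor trials
costs ~10⁻³, so whenever a run's top-scoring trial is an impostor the ±∞
candidate would be optimal — and a single infinite per-run threshold would
poison the arithmetic mean.  Toolkit minDCF implementations sweep observed
scores and have no reject-everything operating point; the finite restriction
reproduces that behaviour.  In practice the retained thresholds all sit just
above (or at) the run's maximum impostor score, which is why the averaged
strict threshold tracks the extreme-value level of ~10⁴-trial subsets.

## Experiments and desk scaling

Every experiment family refits PLDA on the split's known enrollment
recordings, bootstraps the threshold on the same data, runs the attack and
counts outcomes; everything is deterministic given the master seed, with
per-split and bootstrap seeds derived from it.  Preset problem sizes are the
package's desk-scale choices: a 1100-speaker single-task cohort with known
sets of 200/500/1000 against 50 probes (overlap 5 realistic, 50 full), 20
splits per size; clinical-task suites use 400 speakers with known 150 /
unknown 40 / overlap 5, 10 splits, default cost preset, bootstrap subsets of
50 with 100 runs.  These preserve the full-scale design — overlap counts,
split replication, strict-vs-default cost presets, per-split refitting —
at roughly a tenth of the set sizes so a family completes in about half a
minute on one core.

Risk accounting: FAR uses impostor comparisons (total minus overlap) as the
denominator — at attack scales this is numerically indistinguishable from
total comparisons and is the statistically correct base.  Per-run precision
is undefined (reported missing, not zero) when nothing is accepted, and
group means exclude those runs with the exclusion count reported; the FA/TA
ratio of a group is the ratio of mean counts.  Both conventions are
reported because they answer different questions (typical run reliability
vs aggregate count balance) and are not mutually derivable.  Trend tests use
the Pearson coefficient with the exact Student-t two-tailed p-value
(t = r√(df/(1−r²)), df = n−2); no multiple-testing correction is applied.
Score ties at the threshold are accepted (≥ comparison) and ranking ties
break by known-speaker id, so attacks are fully deterministic.

## Known limitations

* Gaussianity end to end: both generator and verifier live in the same
  model family, so verifier calibration is optimistic relative to real
  embeddings.
* The EER operating point of the prose ("threshold where FAR = FRR") is
  implemented as the standard criterion; equal-cost formulations that pin
  the threshold elsewhere are not modelled.
* Pooled probes average all of a speaker's shareable recordings (those not
  in the adversary's enrollment data); alternative linkage models (score
  fusion, per-task weighting) are out of scope.
* Split sampling assumes speakers are exchangeable; demographic structure
  enters only through the stratified search-space arithmetic, not the
  generator.
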