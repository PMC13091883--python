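# Methods

`recallseg` implements a pipeline for studying scene-level memory recall in
naturalistic-listening fMRI: several annotators segment a narrated story into
scenes anchored to recall questions; scene windows define dynamic
functional-connectivity (FC) estimates per subject; each scene's stacked FC is
split into a shared low-rank and an idiosyncratic sparse part; and scene-level
high/low recall labels are classified from each representation under
leakage-aware cross-validation with a label-shuffling null.

## Consensus scene segmentation

Each annotator supplies an ordered, contiguous segmentation of the narrative;
every proposed scene carries the recall-question identifiers anchored to it.
Durations are validated against a 45–120 s admissible range (the range used in
the event-segmentation literature to balance temporal resolution against
stable FC estimation), with a continuity tolerance of ε = 0.5 s on the input.

Proposals from *distinct* annotators with intersecting question sets are
linked, and consensus groups are the connected components of that graph.
Transitive closure was chosen because it is deterministic and independent of
annotator order; the cost is that a proposal can never belong to two consensus
scenes, and an annotator who merges two scenes (carrying both question sets)
will fuse their groups. Groups supported by fewer than `min_support` (default
2) distinct annotators are set aside. Each surviving group becomes one
consensus scene with onset/offset equal to the arithmetic mean of its
members'. "Members" already includes every annotator that proposed a
question-sharing scene, so averaging "over all annotators" would be the same
computation — an annotator with no matching scene has no timings to average —
and no separate switch is needed. Averaged boundaries are then snapped back to an exact
partition of `[0, narrative_duration]`: each adjacent boundary becomes the
midpoint of (previous offset, next onset), the first onset is clamped to 0 and
the last offset to the narrative end. Consensus scenes whose averaged duration
leaves the 45–120 s range are flagged rather than dropped, since dropping
would break contiguity. Ties in scene ordering are broken by
(onset, offset, smallest question id).

## Timing

Acquisition geometry: TR = 1.5 s, 8 lead-in TRs (12 s) before the audio clip,
then a per-story in-clip silence before the narrative. Durations convert to TR
counts by ceiling (400 s → 267 TRs, 536 s → 358 TRs) and TR counts to seconds
by exact multiplication (294 TRs → 441 s, 390 TRs → 585 s). Scene windows are
0-based and half-open, floor on onset and ceiling on offset, so windows
over-cover; where two adjacent windows would overlap by a boundary TR, that TR
is assigned to the later scene. No hemodynamic-lag shift is applied.

## Functional connectivity

Per (scene, subject), FC is the Pearson correlation of all ROI pairs over the
scene's TRs (minimum 3; a constant ROI inside a window is an error). The
strictly-lower triangle in row-major order gives r = (R² − R)/2 edge features;
the full study is a (W scenes × M subjects × r) tensor per network (DMN,
auditory, or both — selectable). No Fisher z-transform and no within-window
detrending are applied by default.

## Low-rank + sparse decomposition

For each scene t the subjects-by-edges matrix `Z_t` is decomposed as
`Z_t = L_t + S_t`: `L_t` low-rank (the stimulus-driven pattern shared across
subjects) and `S_t` sparse (idiosyncratic deviations). The solver is principal
component pursuit, `min ‖L‖* + λ‖S‖₁ s.t. Z = L + S`, by inexact augmented
Lagrange multipliers: alternating singular-value thresholding for `L` and soft
thresholding for `S`, with λ = 1/√max(M, r) by default.

Numerical choices:

* convergence at relative Frobenius residual `‖Z − L − S‖F/‖Z‖F ≤ 1e-7`
  (tight enough that the additivity contract is meaningful, cheap at
  45 × 496 scale — ~30 iterations, milliseconds);
* penalty growth ρ = 1.2 with μ₀ = 1.25/‖Z‖₂. Faster growth (ρ = 1.5)
  can satisfy the residual tolerance before the L/S split itself converges,
  leaving ~1e-3 relative error in `L` on planted problems; ρ = 1.2 recovers
  planted rank-3 + 2%-sparse structure to ~1e-7 at essentially the same cost;
* the constraint residual is *not* exactly monotone: small upticks (at the
  1e-5 scale) follow penalty increases. It does decrease over every
  5-iteration span, which is the property the tests assert;
* SVD signs are fixed (largest-magnitude entry of each left singular vector
  made positive) so outputs are bit-stable;
* the M × r "subjects × vectorized edges" layout makes low rank capture
  across-subject shared structure; a vertically-stacked block layout is
  available behind a flag.

## Recall labels

A subject's score for a scene is the arithmetic mean of their per-question
scores over the scene's questions (missing answers are a hard error by
default, mirroring exclusion for absent recall data; averaging over available
answers is an opt-in policy). Binarization is either a fixed threshold
(default 0.5) or — recommended, and the pipeline default — the lowest-quartile
rule, labelling the lowest 25% of pooled scene scores "low" to match a 3:1
high:low class design. Scene means over 3–5 questions are coarsely discrete,
so ties at the quantile cut are routine; the default `fill` policy fills the
low quota exactly, breaking boundary ties by stable sample order, while the
`high` policy (ties always promoted) is available but can leave the low class
far under quota when the bottom score value is heavily tied.

## Classification and inference

Classifiers: ℓ2-regularized logistic regression, random forest, and linear
SVM (ℓ2). Evaluation is leave-one-out cross-validation, per sample by default
(matching the 1440-sample framing) or grouped per subject — the grouped mode
is recommended since per-sample LOOCV lets a subject's other scenes inform the
held-out scene. Accuracy is mean held-out correctness; balanced accuracy and
AUC come from pooled held-out predictions; the 95% CI is a seeded 1000-draw
percentile bootstrap over per-fold outcomes. The shuffle null permutes labels
within story (preserving per-story class balance) and reruns the full LOOCV
per permutation; with imbalanced labels it centers near the majority-class
proportion, which is reported alongside. Paired comparisons across repeated
runs use a paired t test with zero-variance edge cases handled explicitly.
Calibration uses equal-width probability bins with empty bins flagged. The
SVM has no native probabilities; a logistic squashing of its margin feeds the
calibration bins (AUC uses the margin itself, so ranking metrics are exact).
Logistic LOOCV reuses a warm-started estimator across folds; the problem is
strictly convex, so this changes speed, not results.

## Synthetic studies

The generator emulates the target study's shape: four stories with
{8, 10, 8, 6} scenes and {30, 30, 25, 25} recall questions, 45 subjects per
story (1440 scene-level samples, 180 subjects), five annotators, TR = 1.5 s
with an 8-TR lead-in, and ~25% low-recall labels. Narrative lengths for the
two printed stories are 400 s and 536 s (runs of 294 and 390 TRs, in-clip
silences 9 s and 15 s); the other two stories are not printed and default to
624 s and 468 s — 8 and 6 scenes at the reported 78 s mean scene duration —
with 9 s silences and run lengths derived by the timing arithmetic.

True scene durations are drawn uniform in [45, 120] s and slack-rescaled to
sum exactly to the narrative (rejection keeps every duration in range); each
question belongs to exactly one scene, at least one per scene. Annotators see
boundary jitter (truncated Gaussian, sd 2 s by default, clipped to half the
adjacent duration slack so proposals stay valid and ordered) and may merge
adjacent scenes with probability `split_merge_prob` (default 0), taking the
union of the question sets.

ROI series (R = 32, half DMN / half auditory): within scene t, subject m
receives `x(τ) = √g[m,t] · A_t f(τ) + sparse drivers + σ ε(τ)` with white
latent factors f, white noise σ = 1, and planted rank k = 3. Loadings share a
story-wide base with 30% scene-specific variance — network connectivity
patterns for the same stimulus are similar across scenes, and this shared
direction is what lets a pooled linear classifier read out signal strength.
`g[m,t]` (the subject's expression of the shared pattern) is a log-normal
subject aptitude (sd 0.35) times per-scene log-normal jitter (sd 0.35).
Sparse drivers add correlated input on a random 2% of edges per subject.
Recall couples to the same expression: P(correct) =
expit(logit(0.75) + effect_size · z[m,t]) with z the standardized log
expression, so effect_size = 0 gives labels independent of connectivity at a
75% base rate, and large effect sizes give near-deterministic labels.

What a green end-to-end test establishes: the pipeline recovers planted
boundaries, planted rank, and a planted recall–connectivity coupling under
white observation noise. What it does not establish: robustness to
hemodynamic convolution, autocorrelated or motion-structured noise,
atlas/parcellation error, or real inter-subject variability in network
topography — the generator deliberately models none of these.

## Known limitations

* Real-data headline accuracies depend on restricted fMRI data and are out of
  desk-scale reach; nothing here claims to reproduce them.
* Per-sample LOOCV (the default, matching the emulated design) leaks subject
  identity across folds; use `unit="subject"`.
* The shuffle-null accuracy under class imbalance centers near the majority
  proportion (~75% at a 1:3 ratio), not near 50%; both numbers are reported.
* Connected-components consensus fuses scene groups bridged by a merging
  annotator; with ensembles of ≥4 faithful annotators this is rare but not
  impossible.
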