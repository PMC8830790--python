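# Methods

This note documents the models behind `odorint`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic generators do and do not emulate.

## Plate-assay scoring

A plate is scored from three integer counts: worms in the odor-side strip
(`n_toward`), the opposite strip (`n_away`), and the middle strip.  The
choice index divides the toward/away difference by **all** counted worms,
including the middle area; the alternative convention that divides only by
decided worms is available as `denominator="decided_only"`.  Middle-area
worms count as "no choice", and the incorrect-choice percentage is wrong +
no choice.  In attractant assays the odor side is the correct destination;
in repellent and pairing assays it is the wrong one.

The integration index I = 100·(CI_P − CI_A)/(CI_R − CI_A) is reported
unclamped — over-shooting repulsion legitimately produces values above
100% — and is undefined when |CI_R − CI_A| ≤ 1e−6 (the two single-odorant
assays are then behaviorally indistinguishable and an error is raised
rather than returning an unstable ratio).

Group-level aggregation is not uniquely determined by the per-plate data
model, so both options are implemented: `per_plate` (default) applies the
formula to each pairing plate against the group-mean single-odorant CIs
and summarizes by the median, matching a box-plot-per-assay presentation;
`point` evaluates the formula once on the three group means.

## Calcium quantification

All metrics operate on percent ΔF/F, with F_base the mean raw intensity
over the 10 s before stimulus onset.  Traces with F_base ≤ 0 are rejected
rather than offset: silently shifting a non-physical baseline would change
every downstream percentage.

Windows are left-closed, right-open on the frame grid, and the removal
frame itself is the first candidate for a threshold crossing.  Window
lengths follow the neuron class (10 s for AWB/ASH, 5 s for AVA/AIB/RIM,
second-10-s ON variant for AVA, selectable per call because the choice of
AVA window is panel-dependent).  The latency threshold uses the sample SD
(ddof = 1) of the 10-s pre-removal window; the multiplier (default 3) and
the cap (default 40 s, the recording length the analysis assumes) are
configurable, since other recording protocols will differ.

Group summaries (mean ± SEM per frame) require onset-aligned grids;
grids differing by less than half a frame are snapped to the first trace's
grid, anything larger is an error rather than an implicit resample.

### Detection limit of the 3-SD latency rule

With i.i.d. noise of SD σ, each post-removal frame of a flat signal
crosses the estimated mean + 3·SD threshold with probability ≈ 0.25%.
The false-trigger probability of the latency detector therefore grows
with the number of frames between removal and the true rise — about 1%
per second of hold at 5 frames/s — which sets a practical ceiling on how
long a latency can be measured reliably from noisy single traces.  This
is a property of the published rule itself, not of this implementation.

## Statistical procedure

Normality is assessed per group (D'Agostino–Pearson omnibus; Shapiro–Wilk
below n = 8, where the omnibus test is unreliable; constant samples fail
by definition), and a single failing group routes the whole comparison to
the nonparametric branch.  Because each group is tested at α = 0.05, the
probability that k truly normal groups all pass is ≈ 0.95^k — a property
worth remembering when interpreting branch choices for many-group
comparisons.  Dunnett's test comes from scipy; Dunn's vs-control test is
implemented directly (pooled mid-ranks, tie-corrected variance, two-sided
normal p-values, Bonferroni over the k−1 vs-control comparisons).

## Plate simulator

Worms perform a run-and-tumble walk with tumble rate
λ = λ₀·exp(−β·dS/dt), clamped to [0, 2] s⁻¹, where S is the perceived
signal along the path — the classic pirouette mechanism by which
*C. elegans* climbs gradients.  Defaults: speed 0.015 cm/s, λ₀ = 0.25 s⁻¹,
β = 10, dt = 1 s, 3600 steps (1-h assay), 60 worms starting at the plate
center, 5-cm plate radius, sources ±3.33 cm, azide trap disks of radius
0.5 cm at both spots that freeze worms permanently.

Each odor spot contributes a static Gaussian kernel (σ = 2 cm) instead of
a diffusion solution: no measured concentration landscape exists for the
bench assay, and a static field preserves the one property the behavior
depends on — a smooth monotone gradient toward the source.  Sensory
integration is a linear valence sum, g_att·A_att·G_att − g_rep·A_rep·G_rep
(an optional multiplicative suppression gate exists but defaults off);
blocking of the attractant emerges from repellent dominance.  In pairing
assays both kernels are co-located on the odor side.

Amplitudes are proportional to spotted volume with per-odorant potency.
The defaults (IAA 1 µL → 12, 2-nonanone 1 µL → 40, benzaldehyde
0.02 µL → 11) were calibrated once so that the wild-type preset reproduces
the documented assay outcome — single-odorant |CI| ≈ 0.95–1.0, pairing CI
close to the repellent's, under 8% incorrect choices in all three assay
types — and then frozen.  The repellent-heavy ratio is what makes pairing
resemble the repellent alone; scaling the repellent amplitude through
0.1–2× reproduces dose-dependent blocking.

Genotype presets scale the gains: wild type (1, 1); `osm5_like`
(0.60, 0.18), a cilium-defective phenotype in which single-odorant
chemotaxis keeps its sign (mildly to moderately reduced) while the pairing
response collapses and the integration index drops by tens of points.

Scoring partitions final positions into three equal-width strips
(x = ±R/3); the bench assay's exact area boundaries are not published, and
equal strips keep the middle area's meaning symmetric.  RNG: one seeded
generator per plate (spawned from a master seed), with per-worm draws
vectorized along a fixed worm axis, so batches are reproducible
bit-for-bit and plates are independent.

What the simulator does **not** emulate: odor diffusion dynamics,
worm–worm interaction, starvation state, body mechanics, or absolute
chemotaxis time scales beyond the 1-h horizon.  Passing tests show that
the scoring pipeline is correct and that the paradigm's logic (repellent
dominance, dose dependence, genotype dissociation) is internally
consistent — not that the motility parameters match any particular strain.

## Trace simulator

The deterministic kernel is a saturating exponential toward
f0·(1 + on_amplitude/100) during the stimulus (τ_on = 0.3 s by default)
and an OFF component that starts `off_latency_true` seconds after removal
(τ_off 0.5–5 s by preset), plus i.i.d. Gaussian noise (default 1% of f0).
Sampling is 5 frames/s; epochs are 10 s baseline, 30 s stimulus, 40 s
post-removal — the stimulus duration is a free choice, the other two are
what the analysis definitions require.  The stimulus switches half a frame
before the recorded frame, so the onset frame reflects dt/2 of exposure;
this avoids a one-frame bias in windowed means.

Presets encode the qualitative response patterns per neuron class,
stimulus, and genotype — signs and orderings, not figure-read magnitudes,
which are not published numerically.  For presets with a rising OFF
component, `off_latency_true` is the recoverable event time; ground-truth
latencies are kept at ≤ 2 s (≤ 10 hold frames) as an explicit
detection-budget rule, because the 3-SD rule's false-trigger floor (above)
must stay within the 5% failure allowance of the 95%-recovery target.
Decaying or flat OFF components generate no crossing event, and the
detector correctly reports the 40-s cap for them; their "latency" is not a
recoverable parameter.  osm-5-like variants shrink amplitudes and double
the AWB OFF latency (1 s → 2 s).

Not emulated: photobleaching, motion artifacts, indicator nonlinearity,
and temporally correlated noise.  The i.i.d. noise model is the worst case
for the latency detector (no smoothing), so recovery rates on real,
low-pass-filtered data would if anything be better.

## Problem sizes and numerical choices

Simulation-backed checks use 20 plates × 60 worms per assay type
(~10⁴ worm-hours per batch) and 200 replicate traces per preset for
recovery statistics; Monte-Carlo checks of test calibration use 500–2,000
replicates.  A 200-run estimate of the 95% recovery rate is preferred to a
50-run one because the smaller sample rejects a true ≥95% rate roughly one
time in ten per preset.  Window masks use a 1e−9-s tolerance on frame
boundaries; the integration-index denominator guard is 1e−6; uniform
sampling is enforced within 1e−6 s.

## Known limitations

* The plate simulator's middle-strip geometry and motility constants are
  plausible but not fitted to data; absolute incorrect-choice percentages
  should be read as calibration targets, not predictions.
* The latency detector inherits the published rule's sensitivity to noise
  and hold length; latencies much beyond a few seconds require smoothing
  or a different detector.
* Dunn's test adjusts only over the vs-control family (mirroring
  Dunnett's scope); all-pairs adjustment is out of scope.
* No paired designs, two-way layouts, or effect sizes beyond the reported
  indices.
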