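# Methods

## The mobile-oscillator model

The model asks a narrow question: do synchronized rest/activity cycles reduce
spatial inaccessibility even in a maximally stripped-down setting? It is
deliberately agnostic about *how* ants synchronize — there is no coupling
between agents; synchrony is imposed through the initial phase distribution
and preserved by construction.

State per agent: continuous position in the `L x L` arena (centres confined
to `[r, L − r]` so the whole disc stays inside), a heading, an integer phase
in `[0, 360)`, and two flags (`active`, `has_activated`). Dynamics per time
step: every clock advances 1°, then every active agent attempts one move, in
a freshly shuffled order each step (avoiding fixed-index priority
artifacts; whether the original study moved agents before or after clock
advancement is not knowable from the outside, and the correlation results are
insensitive to it).

Activation is edge-triggered: an agent switches on when its phase *transitions
into* 350°, never by mere membership of the active window. Agents initialized
inside the window therefore stay inactive until their first full pass — all
agents start inactive, which is what produces the high-MLD transient at the
start of every run. Once activated, an agent is active while
`(phase − 350) mod 360 ≤ A`, i.e. `A + 1` steps active and `360 − (A + 1)`
steps inactive per cycle. (Describing the two dwell times as `A + 1` and
`360 − A + 1` would total 362 steps; we use the 360-step cycle, which is the
only reading consistent with the `(360 − 101)/360 = 71.9%` inactivity
identity for `A = 100`.)

Movement: a candidate heading within ±45° of the current one, a unit step,
accepted iff in-bounds and at least one diameter from every other centre.
Each rejected attempt redraws the heading uniformly on the full circle (the
redraw distribution is unspecified in the source description; uniform is the
least-informative choice), up to `retry_cap = 50` retries, after which the
agent stays put for that step and keeps the last attempted heading. A ring of
six touching neighbours provably blocks every unit step, which the tests
exercise.

Phase initialization: populations are resampled until the measured Kuramoto
order parameter is within `r_tol = 0.01` of the target. Rejection from a
*uniform* proposal is only feasible for targets near the `O(N^{-1/2})`
typical value of random phases (≈ 0.09 at N = 120); for R = 0.5 the
acceptance probability is ~1e−11 per draw. We therefore draw proposals from a
von Mises distribution whose concentration κ solves `I₁(κ)/I₀(κ) = R` (so the
*expected* mean resultant matches the target) and reject on the measured R;
this typically accepts within a few hundred draws, capped at 10⁶. `R = 0`
degenerates to the uniform proposal and `R = 1` to a shared random phase
(exact). Initial positions are uniform rejection-sampled without overlap.

Parameters and defaults (study conditions): `N = 120`, `A = 100`, `L = 30`
(length units; 1 unit ≈ 1 mm ≈ one agent diameter), `R ∈ {0.5, 0}`,
4000 steps. The density calibration ties these to real nests: `Da = N/L² =
0.133` agents/unit², agent disc area `π(1/2)² ≈ 0.79` mm² vs a real
`3.0 × 0.4 = 1.2` mm² worker body, and a 120-ant colony in a 19 mm-radius
circular nest at `120/(π·19²) ≈ 0.11` ants/mm².

## MLD

MLD is the count of inactive agents in the fullest sector of a regular grid
partition — 4 × 4 = 16 sectors for the arena, 68-px-square sectors for video
frames (when the frame is not a multiple of 68 px, trailing pixels join the
last row/column sector, preserving the nominal sector size elsewhere).
Sector membership is half-open (`[edge, next)`), with the top/right boundary
closed on the last sector; the convention is tested explicitly. For images
the count is inactive-ant pixels per sector divided by the per-ant body area
(62 px for the smaller species, 80 px for the larger, at the study scale);
the ratio is *not* rounded — nothing downstream requires integer ants, and
rounding would only discard information. pMLD divides by colony size.

## Video activity chain

* **Segmentation**: local adaptive mean threshold on the inverted frame
  (ants dark → foreground), window 35 px (≈ 2 ant lengths at the realistic
  rendering scale), margin 10% of the frame's dynamic range above the local
  mean. A uniform frame yields an all-zero mask with a warning.
* **Activity**: `count(0→1) / count(ants in first frame)` per frame pair;
  disappearing pixels are ignored to avoid double counting. An empty first
  frame produces a missing value (not zero) so correlations skip it.
* **Smoothing**: 15-point Gaussian-weighted moving average, σ = (window−1)/5,
  truncated-window renormalization at the edges (constants pass through
  unchanged).
* **Dominant period**: continuous wavelet transform with the real Morlet
  wavelet (`morl`; the wavelet family is a free choice of the method — any
  analytic Morlet/Morse-class wavelet resolves the 15–200 min band, and the
  choice is recorded in the output metadata), over a geometric grid of 200
  scales spanning periods from `4·dt` to half the record; the period of the
  global scalogram maximum wins. Recovery of synthetic sinusoids across
  15–200 min at dt = 30 s is within 10% (tested), the main error being the
  finite scale grid and edge effects.
* **Cycle segmentation**: peaks above a prominence of 0.25 × the series IQR
  (no principled value exists for this in general; the IQR scaling makes it
  amplitude-free), flanking troughs as cycle starts/ends with the record
  boundaries admitted as troughs; a helper locates the flow-analysis window
  starting 30 s before the cycle midpoint, midpoint = floor((start+end)/2).
* **Event cross-correlation** (e.g. larval interactions): the event series is
  smoothed (window 15) and the Pearson correlation is maximized over lags;
  positive lag means events trail activity.

## Optical flow around inactive ants

Dense flow uses scikit-image's iterative Lucas–Kanade estimator (window
radius 7, 10 warps). Two gates are applied to the magnitudes, in order:

1. **Texture gate.** A windowed least-squares flow estimate is meaningless
   where the window contains no two-dimensional structure; on a flat noisy
   background the system is near-singular and produces arbitrarily large
   vectors. Magnitudes are zeroed where the smallest eigenvalue of the local
   structure tensor (Gaussian-smoothed gradients, uniform window matching the
   flow radius) falls below 2.0 — the classic Lucas–Kanade reliability
   criterion. The threshold sits ~6× above the structure produced by the
   synthetic generator's sensor noise and ~3 orders of magnitude below that
   of an ant edge, so it is insensitive over a wide range.
2. **Noise floor.** Surviving magnitudes below 1.5 px/frame are zeroed, the
   scale of residual flow measured over nest regions with no moving ants.

σPx sums the gated magnitudes over all frame pairs of a clip and is exactly
additive over clip concatenation. Inactive-ant pixels are those
ant-classified in ≥ 90% of a clip's frames (strictly-below-62-px components
removed as fragments of partly-moving ants); the classification is monotone
in the persistence threshold. The random comparison sample is drawn
uniformly without replacement from the whole frame, seeded; the comparison is
a two-sided Wilcoxon rank-sum. The adjacency ring is morphological dilation
with a 10 × 10 square structuring element minus the mask (disjoint by
construction, overlapping rings merged by binary union); the on-vs-beside
contrast is a two-sided Wilcoxon signed-rank over ≥ 5 paired 30-s windows.
Brood-pile crops are fixed at 100 × 150 px (or transposed), tiled by 150
10 × 10 px regions; coverage is the fraction of regions with any supra-floor
flow in a window.

## Synthetic data

The renderer emulates the features the analysis chain actually relies on:
dark oriented elliptical bodies (3.0 × 0.4 units ≈ the real body footprint)
on a light background, additive Gaussian sensor noise (default 2% of the
8-bit range), resting ants pixel-identical across frames, instantaneous
frame samples with no motion blur. Bodies are rasterized at 2× supersampling;
ground-truth masks take pixels with ≥ 50% coverage, each assigned to exactly
one agent. Two scales: 4 px/unit for fast geometric tests and a 12 px/unit
"realistic" preset (~360 px nest, ~36 px ants) matching the 35-px
segmentation window and the 68-px MLD sectors. Body orientation follows the
last displacement and is held through rests.

Brood scenes place resting blobs in a central cluster and movers on
correlated random walks (3 px/frame, jitter 45°) with a 16-px
centre-to-centre keep-out around every blob — roughly one body length of
clearance, emulating ants that skirt a pile rather than brush it. Because
movers physically cannot enter the resting cluster, σPx restricted to the
resting mask is identically zero, giving the detour analyses a known answer.

What the generator does **not** emulate — and what passing tests therefore do
not establish for real footage: occlusions and ants climbing over each other,
larvae and brood items as visible objects, uneven illumination and shadows,
nest-wall texture, leg/antenna motion of "resting" ants, and foraging exits.
Real-video parameters (threshold window, noise floor, per-ant areas) will
need per-setup calibration exactly as in any empirical deployment.

## Problem sizes

Simulation analyses use the full study conditions (120 agents, 4000 steps).
Rendered validation clips use 240 realistic-scale frames; brood analyses use
60-frame scenes and an 8-point sweep of the resting count (two 30-s windows
per scene) — sizes chosen to exercise every code path with comfortable
statistical margins while keeping the whole suite quick on a laptop.

## Known limitations

* The R = 0 activity–MLD correlation is dominated by the all-inactive start
  transient plus the exact identity `inactive count = N(1 − activity)`; its
  value varies substantially between seeds (roughly −0.15 to −0.45 across
  runs at 4000 steps), so single-run comparisons of this number carry little
  information.
* The flow estimator differs from the original study's (iterative
  Lucas–Kanade with a texture gate rather than Farneback polynomial
  expansion); per-pixel magnitudes agree on rigid translations but the two
  methods' noise behaviour differs, which is why flow-derived statistics are
  validated against synthetic ground truth rather than against published
  per-colony test statistics.
* `initialize_population` can fail (with a named error) at densities
  approaching disc packing; the study density (0.133) is far below that
  regime.
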