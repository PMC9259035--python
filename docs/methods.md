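# Methods

## The transport model

A single kinetochore interacts with a single microtubule grown from a
surface-anchored seed; the seed marks the minus end and the origin of the
distance axis.  The model has three regimes:

1. **Lateral transport.**  With probability `p_motile` the kinetochore is
   motile; a motile kinetochore alternates plus-end-directed runs (velocity
   `v_run`, µm/min) and pauses, with exponentially distributed dwells
   (`t_run_mean`, `t_pause_mean`, s).  This is the minimal memoryless
   process consistent with a measured moving-time fraction: occupancy of
   the run state is `t_run/(t_run+t_pause)` and the initial state is drawn
   from that stationary distribution, so occupancy holds exactly at every
   movie length.  Non-motile kinetochores hold position.  Lateral movement
   is strictly plus-end-directed (minus-end excursions of side-bound
   kinetochores are negligible in this system) and the kinetochore never
   detaches.

2. **Microtubule dynamic instability.**  The free plus end grows at
   `v_growth` and catastrophes as a Poisson process (`f_cat`, events/min).
   There is no rescue: after catastrophe the end shrinks at `v_depol_free`
   until it reaches the seed or the kinetochore.  Initial length is uniform
   on `L0_range` (default 2–6 µm, around the ~5 µm physiological target of
   the assay) and the kinetochore starts at a uniform fraction
   (`x0_fraction_range`, default 0.1–0.9) of that length.

3. **End-on attachment.**  When the gap between kinetochore and plus end
   falls below one kymograph pixel (72.2 nm) the attachment converts,
   instantaneously and irreversibly; a run that would overshoot the tip is
   clipped to it.  Conversion also happens to non-motile kinetochores when
   a depolymerizing end reaches them.  From conversion on, the microtubule
   is slaved to the kinetochore: the pair alternates tip-coupled
   depolymerization (`v_tip_track`) and tip pauses (two-state, occupancy
   `t_tipmove/(t_tipmove+t_tippause)`), and the microtubule never regrows.
   Whether tip pausing is a property of the microtubule or the kinetochore
   is not distinguishable in this data; it is modelled as a single
   two-state process.

Events are sampled exactly in continuous time (exponential dwells,
piecewise-linear positions, analytic crossing times for conversions) and
only then discretized to the 5 s frame grid, so dwell statistics carry no
frame-interval bias.  The add-back (rescue) protocol simulates a second
lysate introduced at `t_switch`: every kinetochore still immobile and
lateral at the switch becomes motile with probability `p_rescue = 0.537`
and all kinetics thereafter follow the second preset (exact for
exponential dwells).

## The measurement pipeline

Rendering: the microtubule channel is a line of emitters (one per 72.2 nm
pixel, fractional coverage at the tip), the kinetochore channel a point
emitter; both are blurred with a 1-D Gaussian PSF (σ = 150 nm, a
diffraction-limited TIRF default — the data constrain only relative
geometry), background added (10 counts/px) and Poisson-sampled.
Blinking is an exponential on/off telegraph (on 20 s / off 10 s) applied by
default to the microtubule (red) channel only, since red fluorescent
protein tags blink; the expected-photon image is multiplied by the 0/1
state frame by frame.

Extraction: the kinetochore is followed by an intensity-weighted centroid
in a ±6 px window around its previous position; frames below a 4σ
visibility threshold are flagged and bridged by linear interpolation, and a
track invisible for more than `max_gap` frames raises an error naming the
frame.  The plus end is read per frame as the sub-pixel half-maximum
crossing of the smoothed lattice profile, with blinking gaps interpolated
in time; background is estimated from the empty rows at the top of the
raster (a median over the whole image would saturate at the lattice level
when long microtubules fill the field).

Segmentation: a centred 10-frame least-squares slope is computed per frame
(truncated windows at the track ends).  Frames with slope below one pixel
per window — 86.64 nm/min internally; 86.7 is the conventional printed
value and the difference is below print precision — are paused; the
inequality is strict, so a slope exactly at threshold moves.  Before the
detected lateral→end-on transition (kinetochore within one pixel of the
plus end on two consecutive frames) moving means plus-end-directed
(`run_plus`); after it, minus-end-directed (`tip_track`).  Moving segments
shorter than one full window are below the stated resolution and merge into
the flanking pause.  Per-segment velocity is the least-squares slope over
the segment.

Statistics: per-track velocity is the duration-weighted mean over run
segments only (pauses are reported separately as time fractions); a
gross-displacement velocity is also reported side by side to expose that
interpretation choice.  Run length is the net displacement of one run
segment; cohort run length pools all runs.  Cohort velocities are mean ±
SEM (SD/√n, ddof = 1; SEM = 0 convention at n = 1) over tracks with at
least one run; tracks with no runs still count in the motile-fraction
denominator.  Pooled time fractions are computed over tracks that moved at
all (lateral) or reached the plus end (tip): a never-moving kinetochore has
no run/pause partition to measure.  Histograms use half-open 0.2-unit bins
(edge values go up).  Group comparisons use the Kruskal–Wallis H test with
tie correction (the all-tied degenerate case is reported as H = 0, p = 1);
no multiple-testing correction is applied.

## Calibration of the presets

The generative parameters are **not** the published cohort statistics,
because the measurement is deliberately biased the way manual kymograph
reading is: window smoothing dilutes slopes and widens runs, and the
one-window minimum span truncates the run-length distribution from below.
Each preset was therefore calibrated once, by damped fixed-point iteration
against the *full* pipeline (simulate → render with noise and blinking →
re-extract → segment → summarize; 384-track cohorts, then a bias-removal
pass over sixteen 128-track cohorts), so that the measured statistics land
on the published values; calibration seeds are disjoint from test seeds and
no tolerance or test seed was adjusted afterwards.  Consequences worth
knowing:

* `v_run` generative values sit ~25 % above the measured velocities
  (boundary frames absorbed into run segments dilute the fitted slope).
* `t_run_mean` values (~30–70 s) are well below measured run duration,
  because short runs are either dropped or smeared wider by the window.
* `v_growth` (1.0 µm/min) and the per-genotype `f_cat` are calibrated
  assumptions — the source data do not print them.  Reach-the-end
  fractions are dominated by catastrophe arrival (a kinetochore at
  ~0.17 µm/min net cannot catch a tip growing at 1 µm/min), so the
  calibrated `f_cat` values (~0.004–0.02/min) are far below typical free
  microtubule catastrophe frequencies.  They encode "how often a plus end
  came back to meet its kinetochore in these movies", not a free-dynamics
  measurement.
* `kip3_null` tip-state dwells are carried over from WT: the cohort
  samples too few end-on tracks to constrain them and no printed value
  does either.

## What the synthetic data does and does not establish

The generator emulates the stated acquisition (5 s frames, 30 min movies,
72.2 nm pixels, blinking red channel, shot noise) and the stated biology
(irreversible conversion, no regrowth, no detachment).  It does **not**
emulate: stage drift (inputs are assumed registered), crossed or bundled
microtubules (the QC-exclusion flag is a pass-through hook on synthetic
data), camera gain/offset, chromatic shift, the diffuse fast-moving
population of excess outer-kinetochore protein, force/tension on the
kinetochore, or multi-microtubule geometry.  A green end-to-end test
therefore establishes that the quantification rules are implemented
self-consistently and recover a known generative truth through a realistic
imaging model — not that the model is the only one compatible with the
published data.

## Numerical choices and degenerate inputs

* Conversion tolerance: one pixel (72.2 nm), both in the simulator and the
  detector; detection requires two consecutive close frames to resist
  localization noise.
* Threshold comparisons use the unrounded 86.64 nm/min with a 10⁻⁶ nm/min
  epsilon so that data generated exactly at threshold classifies as moving.
* Segment velocities need ≥ 2 frames; one-frame segments report 0.
* Colocalization: threshold one pixel; "always" requires ≥ 90 % of
  ref-visible frames colocalized (tolerating localization outliers);
  "partially" requires a mostly-apart prefix and a ≥ 90 % sustained suffix
  of at least 5 evaluated frames; anything else — including colocalization
  that ends — is "never".  The published scoring was visual; these are the
  operational equivalents.
* Spindle peaks: prominence ≥ 25 % of the dynamic range, separation
  ≥ 0.5 µm, baseline padding so clusters at the scan ends count; exactly
  two peaks is bilobed, anything else declustered; scans outside the
  2–3 µm spindle-length window are rejected, mirroring the published
  inclusion rule.
* Seeds: cohorts fan a master seed out through `numpy.random.SeedSequence`
  so every trajectory, rendering and analysis stage is independently
  reproducible; identical config + seed gives byte-identical reports.

## Known limitations

* The declustered "multi-focus" fixture occasionally produces two foci
  close enough to merge under noise; classifier accuracy on the fixture is
  ~95–98 %, not 100 %.
* At n = 128 the pooled run-length mean is a heavy-tailed statistic with a
  ~5–10 % seed-to-seed coefficient of variation, and motile/reach-end
  fractions carry ~3–4 point binomial noise; single-cohort values routinely
  sit 1–2 SD from the calibrated expectation.  The one-window minimum-span
  rule also floors the detectable run length, so for short-run genotypes
  the measured mean cannot be pushed below ~0.46 µm by shortening run
  dwells alone.
* The in-cell spindle images themselves are out of scope; the phenotype
  module consumes line scans (supplied or synthesized along a given axis).
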