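# Methods

This note documents the models and numerical choices behind
`choreoquant`: the event definitions, the registration procedure, the
population statistics, and — in most detail — the synthetic
mother-machine generator that the test suite and the acceptance script
run against.

## Coordinates, units and conventions

Long-axis position is stored in pixels with the **new pole at 0** and
the old pole at `L` (polarity coordinates). Derived coordinates are the
signed mid-cell coordinate `u = x − L/2` and the relative position
`r = u/L ∈ [−0.5, 0.5]`. Cell age is `a = frame/(n_frames − 1)` so birth
is exactly 0 and division exactly 1. Event times are reported on the
frame grid as `frame × Δt` with Δt = 5 min by default; no mid-frame
correction is applied. Each cycle also records its orientation in the
microfluidic device (`device_flipped`), which is independent of
polarity: registration works in device coordinates, everything else in
polarity coordinates. Lengths and areas are kept in pixels internally
and converted through `pixel_size_um` (0.065 µm/px) at presentation
time.

Cycle filtering keeps cycles with 10–60 frames inclusive ("less than
10" and "greater than 60" discarded; the upper bound is raised to 80
frames for slower media via the config file).

## Event detectors

* **ori duplication.** First frame with ≥ 2 ori foci. When that frame is
  earlier than `early_lookback_frames` (4) and the mother cycle is
  available, the mother's inherited half is scanned for the first frame
  at which its focus count rose to two, reported as a negative frame
  number. Foci are assigned to mother halves by the per-frame midline;
  the inherited half follows from the daughter's slot in the lineage
  record (daughter 1 = old-pole half, daughter 2 = new-pole half). The
  per-frame midline stands in for the division plane, whose relative
  position is the midline at division; an absolute-position plane would
  be ill-defined at earlier frames when the mother is shorter.
* **ter/MatP centralisation.** A frame qualifies when the MatP focus
  nearest mid-cell lies within the mid-cell window (4.8 px). The event
  is the first frame of the first run of `persistence_frames` (3)
  consecutive qualifying frames. A frame with no detected focus does not
  qualify and, in the default conservative mode, breaks the run; a
  skip-tolerant mode (`skip_missed_frames`) ignores such frames
  instead. With per-frame miss probability `p`, the conservative rule
  caps the fraction of cycles detected within ±1 frame at
  `(1−p)^3 (1+p)` — 0.940 at `p = 0.03` — which is why the noisy-data
  recovery of T_MatP sits just below 95 % while T_ori (no run
  requirement) reaches 99.7 %.
* **Nucleoid constriction.** The relative dip depth of a line profile is
  `(min(a, b) − m)/min(a, b)`, where `m` is the profile minimum over the
  middle third and `a`, `b` are the maxima of the two flanks (searched
  over the whole profile). Normalising by the *smaller* flank makes the
  score 0 for monotone profiles and insensitive to overall intensity.
  The stable-constriction time is the earliest frame from which the
  depth stays above the threshold until division (a suffix scan). The
  default threshold 0.13 matches the configured value used throughout;
  `derive_constriction_threshold` recomputes it as the 95th percentile
  (linear interpolation) of newborn first-frame dip depths, which are
  pure profile noise because newborn nucleoids are unconstricted.
* **ter-sister separation.** First persistent run (same persistence) of
  ≥ 2 MatP foci.
* **Orientation.** Sign of the mean signed MatP position over the first
  up to 4 frames with a detected focus; |mean| < 0.5 px is "unknown".
  This early-frame rule is a reconstruction — the operational definition
  used to produce the published inverted-subpopulation counts is not
  described — and it is deliberately conservative: a cell whose ter
  starts at mid-cell cannot be assigned an orientation.

## Registration

Averaging length-normalised fluorescence profiles over all cells **in
device coordinates** (no polarity flip) must produce a symmetric profile
when no channel offset is present, because cells sit in the device in
both orientations. The mean profile is a Gaussian-kernel density of
focus positions (bandwidth 1 px scaled per cell) on a 141-point grid
spanning the normalised length with 0.2 padding on both sides (so
candidate shifts cannot push edge mass off the grid; the grid is
symmetric about mid-cell so mirroring is an index reversal). The
asymmetry score of a candidate shift is the sum of squared differences
between the shifted profile and its mirror image; the estimate is an
integer grid search over ±4 px followed by parabolic refinement, and is
the correction to *add* in device frame. One offset is estimated per
channel per dataset. Residual bias from averaging per-cell shifts
`offset/L_i` into one normalised shift is below 0.1 px for offsets up to
2 px at the default length distribution.

## Population statistics

Kymographs bin each focus by cell age and by position relative to the
**exponential-fit** length (log-linear fit of length vs frame), which
damps per-frame segmentation noise; each age column is divided by the
number of cell-frame observations in that column, so a value is "foci
per cell" at that age/position and multiplying back by the column count
recovers raw counts exactly (mass conservation, tested). Demographs use
current cell length as the column axis and µm mid-cell offsets as the
position axis. Event-synchronised kymographs index columns by
`frame − t_event`.

Step-wise velocities link foci between consecutive frames by a global
minimum-total-distance nearest-neighbour assignment with a maximum step
of 15 px and an intensity tie-break. The maximum step must exceed the
one-frame ter transit (~0.3 L ≈ 10–12 px in these cells); a tighter
bound would silently drop the very jump the synchronised velocity curve
is built to show. Velocities are `Δu/Δt` in µm/min, signed toward the
old pole, or toward the pole the focus was nearer at the earlier frame
("nearest pole" mode; per-frame nearest, not nearest-at-birth). The
step from `f` to `f+1` is assigned to relative frame `f+1 − t_event`,
so an arrival jump lands in column 0. Standard errors pool individual
steps across cycles.

Nucleoid kymographs average length-normalised line profiles per age
bin; the contour level for a mass fraction is, per column, the
intensity whose super-level set encloses that fraction of the column
total (linearly interpolated between achievable fractions), averaged
over columns.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes;
it is the package's test bed, not a claim about any particular
experiment. Defaults are the slow-growth study conditions.

**Growth.** Cycle duration is a round-to-grid normal, mean 133 min, sd
27 min (sd not printed in the source data; a generator decision),
clipped to the 10–60-frame observable range. Birth length is normal
(1.71 ± 0.17 µm, sd a decision); cells grow exponentially and exactly
double, so the exponential length fit is exact on noise-free data.
Area is length × a fixed 0.7 µm width.

**Event times** are drawn on the 5-min grid:

* `t_ori` — round-to-grid N(26.6, 28.0) min, clamped below at −4 frames
  (−20 min) so mother backtracking is exercised but bounded.
* `Δ = T_MatP − T_ori` — a mixture of a short-lag cluster on 5–25 min
  (geometric decay) and a `30 + Exp` tail, with the three shape
  parameters solved at construction so the pmf has exactly mean 26.5,
  sd 23.2 and grid median 30 (mass below 30 pinned at 0.46). The
  printed combination — median above the mean, sd comparable to the
  mean, hard floor — *forces* a large short-lag mode; roughly 44 % of
  cycles centralise ter within one frame of duplication completion,
  and the remainder follow the long tail.
* `g = T_Nucleoid − T_MatP` — shift + gamma, rounded and floored,
  solved to mean 51.5, sd 38.1, grid median 40.

**Dependence.** A Gaussian copula couples duration and the three
timing draws. The correlation between `t_ori` and `Δ` is −0.49,
*derived* from the printed sds (independent draws would give
sd(T_MatP) = √(28² + 23.2²) = 36.4 min, far above the printed 26.1);
similarly −0.06 between `g` and the upstream draws. Positive latent
correlations with duration (0.30 for the timing draws, 0.60 for `g`)
express that event times scale with the cycle that contains them.

**Feasibility.** Measured event times always fit inside their own
cycle; independent draws do not. Infeasible `t_ori`/`Δ` draws (~1 % of
cycles) are redrawn from the conditional distribution on the feasible
window (inverse-CDF truncation). For the constriction lag the window
`t_nuc ≤ division` binds often — no admissible joint can avoid it,
since keeping sd(g) = 38.1 inside the ~80-min window left after
centralisation would require a correlation above 1 — and overlong lags
are instead **clamped to the cycle end**: a cell whose constriction
would complete after division constricts at division. Clamping leaves
the detected lag median at the printed 40 min, where proportional
redistribution would drag it to 35; the realised lag *mean* lands near
48 min, below the nominal 51.5, which is the honest footprint of
forcing a very dispersed lag into finite cycles. Centralisation is
additionally constrained to at least 1 frame after birth and at least
5 frames before division (there is no mother backtracking for ter, and
stable centralisation needs a 3-frame run before the sisters split).

**Trajectories.** The single ori focus sits at +0.05 L toward the old
pole (the printed ~5 % bias). At `t_ori` it splits; the sisters move
linearly in relative position to ∓0.25 L, arriving *simultaneously* at
`t_matp` — the coupling of ter centralisation to the completion of ori
segregation is built in, with the new-pole sister covering more
distance (0.30 L vs 0.20 L). MatP starts at −0.40 L, drifts to
−0.30 L, jumps to mid-cell in one frame at `t_matp`, stays there until
`t_tersep` (division − 2 frames) and then splits outward. Optional
left/right arm loci sit new-pole-ward of ori and duplicate to inner
positions, reproducing NP-L-O-OP at birth and O-L-L-O before division.
Nucleoid profiles are flat-topped plateaus (super-Gaussian, half-width
0.35 L) whose centroid bias toward the new pole decays to zero by age
0.5, with a central Gaussian dip (σ = 0.08 L) appearing at `t_nuc` with
relative depth 0.20 and ramping by 0.03 per frame.

**Subpopulations and imperfections.** A fraction `p_inverted` (0.007)
of cycles mirrors all loci about mid-cell. A fraction `p_seg_defect`
(0 by default; ≈ 0.46 emulates a segregation-defective labelling
system) keeps a single mid-cell ori focus all cycle and gives MatP only
a transient 2-frame mid-cell visit before its sisters move outward.
Localisation noise (0.5 px), per-focus missed detections (0.03/frame),
a device-frame channel offset, and multiplicative profile noise (4 %)
are applied last. Cycles whose ori duplicated before birth get a
dedicated mother cycle showing the second-initiation focus-count rise
in the inherited half, so negative times are recovered by the same
code path real data would use; mothers are part of the dataset but not
of the ground-truth subject cohort.

**Determinism.** All randomness flows from one `numpy` generator seeded
from `GeneratorParams.seed`; identical parameters give byte-identical
datasets.

## What the generator does and does not establish

Passing tests on this generator show that the detectors invert the
generative event definitions exactly (100 % on noise-free data), that
they degrade gracefully under the modelled noise, that registration
recovers injected offsets, and that the population statistics conserve
mass and reproduce the generative timing statistics at n = 10,000. They
do not validate segmentation or focus localisation (the package
consumes tracked records), nor the biological fidelity of linear
segregation trajectories, Gaussian-copula dependence, or the modelled
noise; real point-spread functions, focus merging, and
tracking errors are not emulated. The frame-grid timing convention
means sub-frame event times are not representable by construction.

## Problem sizes

The acceptance script and the heavy acceptance tests use 10,000-cycle
datasets (the scale at which the grid medians are stable and binomial
errors on fractions are ~0.4 %); unit and property tests use 300–2,000
cycles. A 10,000-cycle generation-plus-detection pass takes a few
seconds without profiles and ~10 s with profiles on one CPU.

## Known limitations

* The detected lag mean (~48 min) sits below the nominal 51.5 min
  marginal mean, as discussed under *Feasibility*; the median is exact.
* The conservative persistence rule caps noisy T_MatP recovery at
  94 %, as discussed under *Event detectors*.
* `classify_daughter_inheritance` requires both daughters to be
  tracked; the generator does not emit daughter pairs, so inheritance
  statistics are exercised on constructed fixtures.
* One offset is estimated per channel per dataset; rotational or
  scaling misregistration is out of scope.
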