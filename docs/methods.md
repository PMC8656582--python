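# Methods

## The measurement being modelled

A self-seeding microwell chip deposits one cell per well: fluid drawn
through a pore in each well bottom carries a cell onto the pore, and the
stopped flow blocks further entry (attached cell pairs still co-enter,
so a few wells hold two or three cells). Protein secreted by the cell
diffuses through the pore onto an antibody-coated PVDF membrane pressed
against the chip; the membrane is exchanged every 24 h, stained, and
imaged, so each phase of a three-day drug study leaves its own spot
array. Because the chip and membranes share one coordinate frame, a
spot's position identifies the cell that produced it.

The package simulates this measurement forward with known ground truth
and analyzes the resulting images blind. Simulation and analysis share
geometry and file formats but no state: counts, transforms, calibration
and background are all re-estimated from pixels.

## Chip geometry

The published chip has 6400 wells on an 8 × 8 mm active area; the grid
is not printed. We fix 80 × 80 at 100 µm pitch — the only square
factorisation consistent with a square area and single-cell wells — and
flag it as a reconstruction. Coordinates are micrometres from the chip's
top-left corner; well ids are row-major; well (0,0) is centred at
(pitch/2, pitch/2). The default raster is 2.5 µm/px (3200 × 3200 px per
chip, a 10 × 10 grid of abutting 320 px tiles), far coarser than the
real 20×/NA 0.45 optics: the algorithms need resolvable blobs, not
optical realism, and a full chip must render and analyze in seconds to
minutes on one CPU. The measurement ROI radius is 35 µm, below half the
pitch so adjacent ROIs never overlap.

## Population model and presets

Each well's cell count is i.i.d. from an occupancy distribution; the
published distribution (2, 92, 4, 3)% for 0–3 cells sums to 101% and is
stored renormalised. Secretor cells (a per-preset fraction) draw a basal
rate from a lognormal with the cohort's published mean and CV; the
lognormal is our choice — the source data show long-tailed positive
distributions without naming a family. Non-secretors get rate 0: any
residual rate above ~0.01 pg/day would clear the 3-SD detection floor at
the default noise level and contradict the preset secreting fractions.

Phenotypes are sensitive / insensitive-low / resistant with default
fractions (0.91, 0.085, 0.005), inside the published ranges (93–89%,
6–11%, <1%). Stimulation multiplies sensitive and resistant secretors'
rates by 2.0 at t1 (expected mean per-cell increase 91.5%, matching the
published "~90% increase, ~10% unaltered" by mixture arithmetic;
we compute the mean of per-cell percent changes, not the fold change of
means — the alternative reading). Inhibition multiplies sensitive cells
by 0.15 at t2 (a sharp drop; no number is published). Viability is
specified as marginal viable fractions per phase (LNCaP: 0.88, 0.78,
then 0.24 under enzalutamide or 0.39 under abiraterone); conditional
survival is the ratio of consecutive marginals, death is permanent and
silences secretion from the phase of death onward.

Two LNCaP baseline presets coexist deliberately: `lncap-basal`
(secreting fraction 0.95, matching ">90% of single cells secreted") and
`lncap-timecourse` (0.53, matching the 53% baseline secreting fraction);
the source reports both without reconciling them. The paired preset
(`lncap-paired`) reproduces the one- vs two-cell comparison: occupancy
(0.7575, 0.1911, 0.0514, 0) yields ≈1223 single-cell and ≈329 two-cell
wells per chip, and per-cell rate means are keyed by occupancy (4.8 and
7.5 pg/cell/day). Its secreting fraction is 1.0: the published group
means are measured means, and a well pairing a secretor with a
non-secretor would read half the per-cell rate, biasing the two-cell
group ~7% low; modelling the secreting subpopulation directly makes the
expected measured means equal the published values by construction.

## Rendering model

Cells are isotropic Gaussian blobs (σ = 4 µm, peak 3000 counts) at
fixed positions jittered up to pitch/4 from the well centre, with an
18 µm minimum separation between co-seeded cells (cells are physical
objects; coincident blobs would also be uncountable by any detector).
Live cells appear in the calcein channel, dead cells in the ethidium
channel, at the same positions across phases.

Each well's membrane spot is a Gaussian of σ = 20 µm (diffusion
broadening) centred on the pore. Its amplitude is normalised so that the
*mean intensity over the measurement ROI* equals the forward calibration
of the well's areal density (total captured mass / ROI area). This makes
fixed-ROI quantification mass-conserving by construction: rendering
followed by ROI-mean inversion is the identity up to quantisation,
neighbour-spot spill (≤ ~0.5%) and calibration-fit error. The
calibration membrane renders uniform discs at densities 0–0.075 pg/µm²
(the arithmetic of 1 µL drops at 0–300 µg/mL over ~4 × 10⁶ µm² spots).

All channels add a constant background (100 counts), Poisson shot noise
and Gaussian read noise (SD 8), and clip to the unsigned 16-bit range.
Membrane mounting is modelled as a rigid transform per phase (rotation
about the chip centre up to ±0.5°, translation up to ±30 µm — below
half a pitch, the identifiability limit of a lattice match). All
randomness flows from one master seed through named substreams, so any
stage re-run alone reproduces its output bit for bit.

What the simulator does **not** emulate: optical PSF structure, membrane
texture and wet/dry stretch, PSA transport physics, uneven illumination,
stage-overlap stitching artefacts, focus drift, or secretor/non-secretor
conversion over time (the published secreting fraction rises after
stimulation; our cells keep their secretor label). Passing recovery
tests therefore demonstrate algorithmic correctness under a clean noise
model, not robustness to every real-world artefact.

## Detection

Counting is per well: smooth with a Gaussian of one cell radius (4 µm),
take the local background from the well ROI's border annulus, threshold
at mean + 4 SD, label connected components inside the well disc, drop
components under 25% of the nominal cell area (100 µm²), and count each
remaining component as its number of intensity maxima with ≥ 10 µm
separation. Peak counting, rather than an area rule, resolves attached
cell pairs: at a threshold 4 SD above background — far below blob peaks —
a single blob's component area varies several-fold with the noise floor,
while its number of maxima does not. A well is viable-occupied when at
least one live-channel cell is detected; cohort viability is
Σ live / Σ (live + dead) over all detected cells. Cells that wander off
the pore are still assigned to their well (assignment is by well ROI,
not pore proximity). On noise-free renders counts equal truth exactly;
at default noise ≥ 98% of wells count correctly.

## Registration

Spot centroids (median/MAD threshold, half-pitch peak separation,
background-subtracted intensity-weighted centroids) are matched to the
well lattice by a coarse grid search over (dx, dy, θ) maximising the
number of centroids within pitch/4 of a transformed well centre —
robust, unlike least squares, to the many wells with no spot — followed
by two rounds of closed-form rigid least squares (SVD/Kabsch) on the
inlier matches. Fewer than 50 detectable spots is an error (the floor is
config-exposed for small chips); a residual above pitch/4 flags the
transform low-confidence rather than failing. Injected transforms are
recovered to ≪ 0.5 px in translation and ≪ 0.05° in rotation. Scale and
shear are deliberately excluded: membranes mount flat, and a lattice
inlier search cannot separate sub-percent scale drift from noise at this
spot density.

## Quantification

The calibration model I(ρ) = I_bg + I_max·ρ/(ρ_half + ρ) is monotone,
saturating (membrane chemistry saturates) and admits an exact closed-form
inverse. It is fitted by least squares to ≥ 4 standards including a
zero-density anchor; fits with non-positive I_max or ρ_half, or standards
whose means decrease beyond noise, are refused. Every well gets an ROI at
its transformed pore position whether or not a spot is visible — the
empty and below-background wells are data, not absences. Background
statistics are the mean/SD of empty-well ROI means (wells the detector
called empty, ≥ 50 of them); "above background" means exceeding that mean
by 3 SD, the conventional limit-of-detection choice. Intensities at or
below the fitted I_bg map to mass 0 (censored below-range — rates are
physical, never negative); intensities at or above I(ρ_max) are reported
at the range ceiling and censored above-range. The fixed ROI stands in
for per-spot area segmentation, which is unstable for faint spots.

## Dynamics and statistics

Per-well trajectories join the three phases' quantifications; the
per-cell divisor is the phase's live count (falling back to the t0 count
for dead wells, whose masses are ~0 anyway), and alive flags are
monotone by construction. Classification thresholds — stimulation fold
≥ 1.5, inhibition drop ≥ 30% — sit halfway between the simulated effect
sizes (2.0×, 85%) and the null (1.0×, 0%), and are config-exposed; any
trajectory the rule cannot place is `unclassified` rather than forced.
The cohort stimulation statistic is the mean per-cell percent change
over wells viable at t0 and t1 and above background at t0.

The Wilcoxon signed-rank test discards zero differences (Wilcoxon's
original treatment), midranks ties, and uses the exact null of W⁺ for
n ≤ 25 — computed by convolution over doubled midranks, identical to
enumerating all 2ⁿ sign assignments — and the tie- and
continuity-corrected normal approximation beyond. Welch's t
(Satterthwaite df) is provided for between-group viability comparisons
across runs; within a single chip the replicate-level t-test of the
source protocol has no analogue. Quartiles use linear interpolation
between order statistics (type 7); significance stars follow the assay
convention (* p < 0.05, ** p < 0.001, *** p < 0.0001). No
multiple-testing correction is applied, matching the source protocol.

## Problem sizes and numerical choices

Recovery studies run at full chip scale (6400 wells, 3200² px, ~6900
cells) in roughly 10 s each for simulation and analysis; unit tests use
20 × 20-well chips (2 × 2 mm) that run in ~1 s. Noise-free checks use
the same renderer with read noise 0 and Poisson off. Tolerances: 2% for
the calibration round trip (quantisation + fit error), 0.5 px for
registration recovery, 10% relative for cohort-mean recovery (sampling
error at ~5000 wells is ~1%; the rest is headroom for detection and
censoring effects). Ties in nearest-well assignment cannot occur for
points strictly inside a well; boundary points resolve by rounding.

## Known limitations

- Counting saturates around 3–4 cells per well; dense clumps under-split.
- The occupancy readout uses live + dead counts, so a cell dead in both
  channels' blind spots (not modelled) would be missed.
- Registration assumes < half-pitch mounting offsets; larger offsets
  alias to a neighbouring lattice solution.
- Quantification above ρ_max is censored, so extreme secretors are
  reported at the range ceiling rather than extrapolated.
- Cohort statistics treat a well as a cell for multi-cell wells' fold
  changes (the per-cell rate is the well mean).
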