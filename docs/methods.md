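# Methods

This note documents the models and estimators condensakit implements, the
defaults it ships, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Turbidity cloud points

A solution that demixes on heating (LCST regime) turns turbid at its cloud
point T_c. The input is an absorbance ramp A340(T) on a strictly
increasing temperature grid (nominally 1 °C min⁻¹, 0.2 °C spacing in the
synthetic ramps). T_c is the temperature of the maximum of the first
derivative of the curve. Numerics:

- the curve is smoothed with a centered moving average (default 5 points;
  the window is a parameter because instrument-curve differentiation is
  otherwise noise-dominated), then differentiated with `np.gradient`
  (centered differences, one-sided at the ends);
- the **noise floor** of the derivative is a robust MAD estimate of the
  derivative's scatter about its own 5-point local trend — using the
  local trend rather than the global median keeps broad transitions
  (width of a few °C) from being mistaken for noise;
- flags: `flat` when the derivative peak is below 5× that floor (no
  transition; T_c is NaN), `edge` when the maximum of the smoothed *or
  raw* derivative sits on a grid boundary (transition probably outside
  the ramp; the raw derivative matters because edge padding flattens the
  smoothed tail), `clear` otherwise;
- the estimate is invariant under affine transforms of A340, and the
  noiseless recovery bias is below the grid spacing for transition widths
  0.5–3 °C anywhere on the grid.

At 2% amplitude noise the Monte-Carlo scatter of T_c over 200 replicate
ramps is ≈ 0.35 °C with the default window (computed by the test suite and
the acceptance script).

## Partition coefficients

The dense-phase protocol measures the light phase directly and the dense
phase after a D-fold dilution that dissolves the condensates (default
D = 9). P = c_dense_measured · D / c_light. When standard deviations are
supplied, the s.d. of P follows the first-order delta method with
independent errors; when ≥3 replicate measurements exist, replicate-level
s.d. should be preferred over propagated s.d. HPLC peak areas convert to
concentrations through an OLS line over ≥4 calibration standards, inverted
for prediction; areas outside the calibrated range are flagged as
extrapolation rather than rejected.

## FRAP

Three ROI traces are recorded: the bleached region, a whole-cell region
and an extracellular background. The double normalization

N(t) = [(I_bleach − I_bg) / (I_whole − I_bg)](t) ÷ ⟨same ratio⟩_prebleach

cancels acquisition bleaching (which multiplies both numerator ROIs
equally) and scales the pre-bleach level to 1. Frames where the
background-corrected whole-cell signal is non-positive are dropped with a
log entry; a trace with no usable frames is an error.

Recovery for t ≥ 0 (t = 0 fixed at the first post-bleach frame) is fitted
by least squares to the single-exponential model
N(t) = I₀ + (F∞ − I₀)(1 − e^(−kt)); mobile fraction = (F∞ − I₀)/(1 − I₀),
t½ = ln 2 / k. A single exponential (rather than two) is used because the
package reports one (mobile fraction, t½) pair per trace, matching the
easyFRAP convention. Initial guesses are deterministic and derivative-free:
I₀ from the first post-bleach point, F∞ from the mean of the last 10% of
frames, k from the time at which the trace first crosses halfway between
them. A fit with F∞ < I₀ is flagged immobile; a mobile fraction outside
[0, 1] is clipped and flagged; a trace indistinguishable from 1 throughout
(no bleach) is a degeneracy error, as is k ≤ 0.

Round-trip accuracy with the default acquisition design (20 pre- + 200
post-bleach frames, 180 ms spacing): noiseless recovery is better than 1%
everywhere on a mobile-fraction × t½ grid (0.2–0.95 × 0.5–10 s). At 2%
intensity noise the *median* error over that grid stays below 10%; the
fastest cells (t½ = 0.5 s spans ~3 frames) carry irreducibly larger
per-fit scatter (~7% median, ~15% at the 90th percentile for mobile
fraction 0.2), so the grid median — not each cell — is the contract.

## Imaging quantification

Conventions: 0-based pixel-center coordinates, y down; areas reported in
px² and µm² via the pixel size (nm); 8- and 16-bit inputs accepted.
Manual steps of interactive macro workflows (ROI drawing, nucleus
exclusion) are explicit inputs here, so runs are deterministic.

- **Nuclear segmentation**: median filter (radius 3 px) → rolling-ball
  background subtraction → Otsu or local-mean threshold. The rolling ball
  is implemented as grey opening with a flat disk of the ball radius (the
  ImageJ subtract-background idiom); skimage's intensity-coupled ball is
  not used because it erodes plateau-shaped nuclei at these intensity
  ranges. Dark intranuclear holes are treated as nucleoli and stay
  excluded when their mean intensity is below a settable fraction
  (default 0.6) of the surrounding nucleus mean; brighter holes are
  filled. Touching nuclei are *not* watershed-split — over-merged objects
  can be dropped with an area ceiling. Labels are renumbered in raster
  order of their bounding boxes so output is deterministic across library
  versions. An all-zero image yields zero labels; saturated images only
  warn.
- **Granularity**: per-label mean and *population* s.d. (divisor n) of
  the original intensities. With thousands of pixels per nucleus the
  population/sample distinction is immaterial; it is fixed for
  reproducibility and checked exactly against a pixel-loop oracle.
- **Cytosolic condensates**: per timepoint, maximum z-projection →
  cytosol mask (supplied, or permissive Otsu with filled holes) minus the
  nuclear mask → threshold (Otsu within the cytosol or fixed) → connected
  components ≥ min_area. Counts, per-object areas, cytosol area (µm²) and
  count density (µm⁻²) are reported; counts are invariant to whole-pixel
  translation and to intensity rescaling above threshold.
- **Translocation**: per frame, sum z-projection, optional
  translation-only registration to frame 0 (phase correlation; rotation
  is unnecessary for nuclear drift and is not attempted; a failed
  registration falls back to the unregistered frame with a warning), mean
  intensity per ROI, and relative nuclear localization
  I_nuc/(I_nuc + I_cyto). The bounded ratio (not I_nuc/I_cyto) is used so
  values read as fractions in [0, 1]; this choice is a documented
  interpretation, not the only possible one.
- **Nuclear clusters**: nuclei from the DNA counterstain (Otsu, holes
  filled); in the target channel the rolling-ball background with ball
  radius = 8 × resolution limit (e.g. 8 × 48 nm = 384 nm, i.e. 8 px at
  48 nm px⁻¹) is subtracted and the residual Otsu-thresholded within the
  nuclei. Cluster mean intensity and size (nm²) are reported; a
  resolution limit below the pixel size is rejected. On generator fields
  with spot contrast ≥ 5× the background s.d. the fixed-seed suite
  measures recall ≥ 0.95 with ≤ 5% false positives.
- **Droplet partitioning**: droplet mask from the channel-sum image with
  a fixed lower threshold of 3 per channel on the 8-bit scale (upper
  bound 255), rescaled proportionally for 16-bit data; objects kept when
  the *equivalent diameter* is ≥ 0.1 µm (an area reading of "0.1 µm"
  would be sub-pixel at the relevant magnifications); per-droplet mean
  intensity of the probe channel, and an optional peak-normalized
  horizontal cross-section profile.

## MD ligand-contact analysis

A residue contacts the ligand in a frame when at least one heavy
(non-hydrogen) atom of the residue is within 6.0 Å — *inclusive*, ties
being measure-zero in real data — of a ligand heavy atom. Hydrogens are
identified by the element field when present, else by an atom-name
first-letter fallback. Distances are minimum-image when box vectors are
present. Topologies are PDB; trajectories are anything MDAnalysis reads
(XTC/DCD/multi-model PDB) or a plain-text `frame,atom,x,y,z` table; a
frame stride is a parameter because it is not knowable whether a given
published analysis used every frame. When replica-exchange data are
analyzed, only the ground-temperature replica should be supplied.

The bound fraction f_B is the fraction of frames with ≥ 1 contact
anywhere, so f_B ≥ max_i p_i always. Standard errors use
Flyvbjerg–Petersen blocking: the series is repeatedly pair-averaged; each
level records s.e. = sqrt(var/n_blocks) and its own sampling uncertainty
s.e./sqrt(2(n_blocks−1)); the reported value is the first level whose
increase over the previous one is within that uncertainty, with a
conservative fallback (max s.e. over levels keeping ≥ 32 blocks) if no
plateau is found. On correlated binary chains with known integrated
autocorrelation time τ this matches the effective-sample-size formula
sqrt(p(1−p)(1+2τ)/n) within 15% at n = 10⁵.

For a single protein–ligand pair in a closed cubic box of side L, one
molecule corresponds to C₀ = 1/(N_A·L³) (3.936 mM at L = 7.5 nm), and with
[P] = [L] = (1−f_B)·C₀, [PL] = f_B·C₀:

K_D = C₀ (1 − f_B)² / f_B

(1.968 mM at f_B = 0.5). This is the standard closed-box conversion; a
volume correction excluding the protein would shift K_D by a constant
factor, so raw f_B is always reported alongside K_D to keep the conversion
auditable. The delta-method s.e. uses dK_D/df_B = C₀(1 − 1/f_B²). f_B ∈
{0, 1} is rejected (K_D undefined / zero-variance).

## Statistics

**Granularity model.** OLS of within-nucleus s.d. on mean intensity,
group, group × mean interaction and biological replicate (fixed effect, as
a covariate rather than a random effect; with a single replicate level the
term is dropped with a warning rather than fitted singular). The group ×
mean interaction coefficients under treatment coding are exactly the
per-group differences in the s.d.-vs-mean slope relative to the control;
they are tested with a Dunnett many-to-one adjustment over the family of
group contrasts. Requires ≥ 2 groups including the control and ≥ 3 nuclei
per group.

**Dunnett adjustment.** Adjusted p_i = P(max_j |T_j| ≥ |t_i|) under a
multivariate t with the contrasts' correlation matrix and the residual df.
There is no closed form for general correlation, so the tail probability
is integrated by seeded quasi-Monte-Carlo: 2¹⁶ scrambled Sobol' points
through the Gaussian copula (eigenfactorization, so singular correlation
matrices are handled), one chi-square scale draw per point. Accuracy is
~1e-4; a single contrast short-circuits to the exact two-sided t-test, and
the adjusted p is floored at the raw p. Calibration: over 500 seeded null
simulations the familywise rejection rate at α = 0.05 is ≈ 5%; with
independent contrasts the adjustment matches the Šidák limit
1 − (1 − p)^m within 1e-3; perfectly correlated contrasts collapse to the
raw p.

**Log-logistic dose-response.** f(x) = d/(1 + exp(b(ln x − ln e))), lower
limit 0, fitted by nonlinear least squares with bounds (b > 0 enforced up
to 50; d, e > 0); zero-dose controls enter as x → 0 limit observations of
d rather than being dropped. IC50 = e; IC10 is the dose giving 10%
inhibition relative to the upper asymptote, e·9^(−1/b) (the `drc` ED
convention; stated because "IC10" alone is ambiguous). Degeneracies:
responses that do not vary are non-identifiable (error); fewer than 4
distinct positive doses are rejected. At 5% noise (of d) over 6 doses × 3
replicates the median IC50 error across 500 seeded fits is ≈ 8%.

**Small utilities.** ChromLogD = 0.0857·CHI − 2 (chromatographic
hydrophobicity index at pH 7.4); fold change 2^−ΔΔCt with
ΔCt = Ct_target − Ct_reference per condition; ovoid volume
L·W·H·0.5236 mm³ from caliper axes.

## Synthetic-data generators

Every generator is a pure function of its arguments including the seed
(bit-identical regeneration), returns the ground truth alongside the data,
and uses additive Gaussian noise. Gaussian noise is a deliberate
simplification — downstream estimators are validated by parameter
recovery, not by noise realism, and a Poisson shot-noise model would add
a parameter without changing what the tests demonstrate. Defaults encode
the study conditions the analyses assume: FRAP traces default to 20 pre- +
200 post-bleach frames at 180 ms with reference kinetics (mobile fraction
0.94, t½ 2.29 s); turbidity ramps default to a 34 °C midpoint on a
20–50 °C, 0.2 °C grid; contact trajectories default to a two-state Markov
chain whose stationary bound fraction and integrated autocorrelation time
are stored in the truth record; dose-response tables default to IC50
1.5 µM with hill slope 1 and 3 replicates. Where the source protocols
state no noise magnitude, noise levels are exposed as parameters rather
than fixed.

Emulated vs not: nuclei are ellipses with Gaussian bright spots under a
Gaussian PSF — no optics beyond Gaussian blur, no chromatic effects;
condensate time-lapses nucleate disks at a Poisson rate and grow linearly
in area — no coarsening/Ostwald kinetics or fusion; toy MD trajectories
alternate a ligand between a bound pose (5 Å from a designated residue)
and a far pose, with hydrogens placed *closer* than the heavy atoms in the
bound pose specifically so contact code that fails to exclude hydrogens is
caught. A latent "bound" Markov frame emits contacts per-residue
independently, so if every profile entry is < 1 the observed bound
fraction is f_B*·(1 − Π(1 − p_i)); the truth record stores both the latent
and the observed value. Passing tests therefore demonstrate estimator
correctness and calibration under the assumed data-generating models, not
robustness to microscope- or force-field-specific artifacts.

## Pipeline plumbing

TIFF stacks are read/written with axes normalized to (t, z, y, x, channel)
and the pixel size (nm) taken from resolution metadata (an absent pixel
size is an error unless overridden, because the physical-unit
quantifications need it). Ground truth travels as a YAML sidecar next to
the data. `run_pipeline` executes one configured stage: unknown config
keys are rejected before any computation, the resolved config is written
next to the outputs, every run logs the package version and config hash,
and a manifest records sha256 hashes of inputs and outputs; a failing
stage leaves a `.failed` marker. All randomness flows from the config
seed. Problem sizes in the test suite and acceptance script (200 turbidity
replicates, 500 dose-response fits, 10⁵-frame chains, 3 detection fields)
were chosen so each stage's sampling error is well below the tolerance it
is tested against.

## Known limitations

- No diffusion-equation or reaction–diffusion FRAP models; traces whose
  recovery is not single-exponential will show it only as residual RMSE.
- Segmentation quantifies projections; there is no 3-D segmentation,
  deconvolution or lifetime filtering.
- The cloud-point extractor assumes the LCST orientation (absorbance
  rising with temperature); UCST-style ramps should be negated first.
- The Dunnett integration is exchangeable-correlation-exact only in the
  QMC limit; p-values below ~1e-5 are resolution-limited by the 2¹⁶
  sample size and reported at the raw-p floor.
- The K_D conversion ignores excluded volume; comparisons across box
  sizes should use the stored f_B values.
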