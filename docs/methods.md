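# Methods

## What is being modelled

A bench GASMAS measurement of a simplified lung phantom: a gridded array of
229 glass capillaries, some holding air (inflated alveoli), the rest filled
with a liquid phantom matching lung optical properties, enclosed in a
chamber at body temperature and high humidity. A dual diode laser scans the
O₂ line near 760 nm and an H₂O line near 820 nm in transmission through the
array; the instrument output is a second-harmonic (2f) wavelength-modulation
amplitude per gas. The package simulates that output for configurable
air-volume configurations and runs the standard two-wavelength inversion on
it, so the full inference chain — including its failure modes — can be
studied without hardware.

## Geometry and volume budget

The grid is 20 columns along the beam × 12 rows; column pitch is the array
span divided by the column count, 0.025 m / 20 = 1.25 mm, which equals the
capillary outer diameter (the tubes touch). The beam-sampled volume is
width × depth × span = 0.01 × 0.014 × 0.025 m = 3.5 × 10⁻⁶ m³. Two lengths
are not directly printed on the physical build and are fixed by consistency
with its reported volumes, both configurable:

- outer radius 0.625 mm, so the 229-capillary envelope volume is
  2.81 × 10⁻⁶ m³;
- sampled capillary length 0.01 m (the detector aperture side), so one bore
  holds π r² L = 1.96 × 10⁻⁹ m³ of air.

The interstitial air (sampling volume minus envelope volume,
6.90 × 10⁻⁷ m³) is constant across configurations; total air is interstitial
plus bore volume of the air capillaries. Volume conservation
(air + liquid + glass = sampling volume) holds to 1 × 10⁻¹² relative for
every fill state and is property-tested.

The consistency report recomputes the 22-row air-volume table (two sweep
sets, steps of 20 capillaries) and compares it, after round-half-even to two
decimals in units of 10⁻⁶ m³, with the printed reference values. Three
printed rows deviate from the uniform step arithmetic (set 1 at 80 and 180
converted capillaries, set 2 at 140); they are flagged, never silently
matched.

## Gas path model

Light is modelled as straight rays, one per grid row, each crossing every
column cell of its row. Through an air bore at lateral offset y the ray
accumulates a chord 2√(r² − y²); the expected-mode path uses the analytic
mean over uniform offsets — mean chord (π/2)r times hit probability
2r/pitch, i.e. πr²/pitch per air capillary — and the interstitial
contribution per cell is pitch − π r_out²/pitch. Vacant holder cells (the
grid has 11 more cells than capillaries) count entirely as interstitial air.
A Monte-Carlo sampled mode draws offsets explicitly; its mean agrees with
the expected mode within 1% at 10⁵ rays (tested). The true gas path of an
acquisition is the beam average over all rows; for the all-air configuration
it is 9.26 mm, below the geometric single-ray maximum of 10 mm
(columns × bore diameter, the envelopes being contiguous).

Multiple-scattering path enhancement, the defining complication of GASMAS in
real tissue, is collapsed into a single multiplicative factor
(`simulation.path_enhancement`, default 1). This is a declared limitation,
not a model of photon migration: absolute path lengths are only meaningful
relative to that factor. Interstitial air contributes to the gas path by
default (it is counted in the phantom's air volume); a config switch
(`simulation.include_interstitial`) disables it.

## Forward signal model

Per gas the noiseless 2f trace is

    amplitude(ν) = wms_gain · ε · c · l · H₂(ν),

where H₂ is the second Fourier coefficient of a peak-normalised Lorentzian
under sinusoidal modulation, (2/π)∫₀^π L(ν + mγ cosθ) cos 2θ dθ, evaluated
by 64-node Gauss–Legendre quadrature (agrees with a 10⁵-point Riemann sum to
1 × 10⁻⁶) and normalised so its maximum absolute value over a dense grid is
1 with a positive centre lobe. Defaults: halfwidth γ = 1 detuning unit,
modulation index m = 2.2 (the classic 2f optimum), 201-point grid spanning
±6 halfwidths.

The linearisation amplitude ∝ absorbance is valid because ε c l ≪ 1 in every
simulated regime (≈10⁻³ at the defaults); the real instrument's 2f transfer
function is proprietary. The effective absorptivities (O₂ 1.0, H₂O 4.0 per
unit fraction per metre) and the gain (1000 instrument units per unit
absorbance) are order-of-magnitude placeholders shared between the forward
and inverse modules through one config block: parameter-recovery results are
therefore self-consistency statements, and absolute spectroscopic accuracy
(line strengths, Voigt shapes, the 935 nm water line) is out of scope.

Bulk transmission — reported alongside the scans but not folded into the 2f
trace, as 2f amplitudes are conventionally normalised to the DC level — is
exp(−μeff · n · chord) with μeff = √(3 μa(μa + μs′)) = 297.5 m⁻¹ at the
default optics, n the beam-averaged number of phantom-filled capillaries
crossed and chord the mean envelope chord (π/2) r_out.

Noise is additive zero-mean Gaussian on the trace with SD equal to
`simulation.noise_sd` (default 3%) of the trace maximum. With peak read-out
this produces pooled concentration SDs of order 0.5 percentage points in a
stable chamber and 1–1.5 points under drift (see below) — the same order as
bench-reported spreads of 2–3 points.

## Environment and drift

Water concentration is the mole fraction RH/100 · e′w(T, P)/P with the Arden
Buck saturation pressure in hPa/°C convention (63.06 hPa at 37 °C and
1013.25 hPa; 62.80 hPa without the pressure enhancement factor, matching the
textbook value). A number-density convenience via the Boltzmann constant is
provided. The nominal chamber default is 37 °C / 92% RH / 1013.25 hPa: the
physical chamber's humidity controller oscillated between 90 and 94% RH, so
the midpoint is the realistic operating point; the physiological ideal
(100% RH) is one config key away.

Drift draws T and RH independently and uniformly over (36, 39) °C and
(90, 94)% per acquisition, seeded by `rng_seed + acquisition_index`. Only
ranges were reported for the bench chamber, so no temporal correlation is
modelled. The inversion always assumes the nominal environment; the
drift-induced mismatch is the intended error mechanism (temperature
dominates: d ln e′w/dT ≈ 5.5%/K at 37 °C), and it is what makes the set-1
emulation strictly noisier than the stable set-2 emulation.

## Inversion and QC

Quantification is peak-based (maximum absolute 2f amplitude), matching how
the bench data were analysed; no lineshape fitting is performed. Path:
l = peak_H₂O / (gain · ε_H₂O · c_H₂O(assumed env)); concentration:
c_O₂ = peak_O₂ / (gain · ε_O₂ · l). Noiseless round trips recover truth to
machine precision for every configuration. RH = 0 raises an explicit
"unrecoverable path" error — high humidity is a precondition of the method.

QC flags any record whose inferred path exceeds the geometric single-ray
maximum (no safety margin by default; `simulation.qc_multiplier` scales the
threshold). Flagged records are excluded from all means and SDs but retained
in the record output, reproducing as behaviour the bench study's exclusion
of an anomalously over-absorbing configuration. Under drift the hot-chamber
draws organically flag ~5% of set-1 acquisitions at the largest air volumes.
An `anomaly_configs` hook in the experiment runner scales the simulated H₂O
trace to exercise the rule deterministically in tests.

## Statistics conventions

Pooled concentration summaries use the arithmetic mean and sample SD (n − 1)
of the per-acquisition inferred O₂ across all unflagged records of a set —
per-acquisition inference first, pooling second (whether the bench system
averaged before or after inversion is unreported; this choice is documented,
not inferred). A single-record SD is reported as 0 with a warning. Each
configuration is acquired 10 times by default; the default simulated truth
is 20.9% O₂ (ambient air in the chamber — bench-reported absolute
concentrations reflect an unpublished instrument calibration and are not
reproduction targets).

## Seeds and reproducibility

One master seed is split into independent sub-seeds (fill allocation, drift,
per-acquisition noise) via `numpy.random.SeedSequence` hashing of
(master, set, purpose, configuration, replicate), so modules are testable in
isolation and a whole run is byte-reproducible from the config file and seed
alone; both appear in every output header.

## What the synthetic generator does not emulate

- photon migration (no Monte Carlo transport; path enhancement is a scalar),
- capillary wall refraction and the resin holder,
- Voigt lineshapes, 1f/residual-amplitude-modulation backgrounds, detector
  electronics and absolute radiometry,
- temporal structure in chamber drift and tidal (time-resolved) breathing.

A green test suite therefore establishes internal consistency of the
geometry–forward–inverse chain and the qualitative bench trends (signal and
transmission falling with liquid-filled count, drift inflating the spread),
not agreement with any specific instrument's absolute output.
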