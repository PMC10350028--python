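# Methods

## Model and assumptions

The package treats an atom as a single isotropic Gaussian scatterer with
electron count Z and total width B (Å²),

    ρ(r) = Z (4π/B)^{3/2} exp(−4π²r²/B),

normalized so ∫ρ dV = Z; the prefactor follows from that normalization and
fixes ρ(0) = Z (4π/B)^{3/2}. The total width splits as B = B₀ + B_iso. The
approximation underlying everything downstream is that the *shape* of the
atomic scattering factor is independent of Z — substituting one neutral
element for another changes only the Gaussian's weight, not B₀. This is
good across the first rows of the periodic table (B₀ moves only from ≈8 Å²
for N to ≈6 Å² for S) and degrades for heavy elements.

Both compensation models are ratio-only: B₂ depends on Z₂/Z₁, never on the
absolute normalization of ρ. Model 1 (equal peak density) matches the map
value at the atomic center, a local criterion close to what a
restrained-coordinate B-only refinement sees. Model 2 (least integrated
squared difference density) is a global criterion over the isolated atom's
entire volume; its closed form B₂ = B₁ u^{2/5}/(2 − u^{2/5}) diverges at
u = 2^{5/2} ≈ 5.657, where no finite B₂ can minimize the mismatch. The
divergence is a hard domain error, not clamped or continued.

## B₀ extraction

B₀ is defined operationally: compute the true peak density of the
multi-Gaussian scattering-factor table broadened by a reference
B_iso = 16 Å² (a typical macromolecular value),

    ρ(0) = Σᵢ aᵢ (4π/(bᵢ+B_iso))^{3/2} + c (4π/B_iso)^{3/2},

then solve Z (4π/(B₀+B_iso))^{3/2} = ρ(0) for B₀ in closed form. The
constant term c of the X-ray parameterization is treated as a zero-width
Gaussian, broadened by B_iso alone. This choice matters: c is large and
negative for N (−11.53), and the alternative (ignoring c's broadening)
would not reproduce the accepted B₀ ≈ 8 Å² for nitrogen. Because the c term
diverges as B_iso → 0, B_iso must be strictly positive. B₀ drifts slowly
with the reference B_iso; 16 Å² is the package default throughout.

## Coefficient tables

Two editions are embedded as a versioned CSV with provenance strings:
the 4-Gaussian+constant X-ray Cromer–Mann coefficients (International
Tables Vol. C, Table 6.1.1.4; neutral atoms H, C, N, O, Na, Mg, Al, Si, P,
S, Cl, Ca, Fe, Se) and the 5-Gaussian electron parameterization of Peng,
Ren, Dudarev & Whelan (Acta Cryst. A52, 1996; H, C, N, O, P, S, Fe).
Convention: s = sinθ/λ in Å⁻¹, widths bᵢ in Å², temperature factor applied
as exp(−B s²). Two independent integrity checks run in the test suite:
the neutral-atom sum rule |Σaᵢ + c − Z|/Z < 1% for every X-ray row, and a
Mott–Bethe cross-check fₑ(s) ≈ (Z − fₓ(s))/(8π²a₀s²) linking the two
radiations at s ∈ {0.3, 0.5} Å⁻¹ (observed agreement ≲0.3%, asserted at
1%). A transcription error in either table would break the second check.
Several electron-parameterization variants exist in the literature; the
<2% C/N/O contrast result is insensitive to the choice at this level.
Electron peak values are reported in parameterization-native units; only
relative comparisons are meaningful for that radiation.

Peak-density contrast is reported two ways, because both conventions are
used when quoting "X differs from Y by p%": the headline spread is
(max−min)/mean, and the pairwise matrix divides by the smaller value. For
X-ray C vs O at B = 16 Å² these give 42.9% and 54.6% respectively — both
rounding to the conventional "≈50%".

## Numerical verification of model 2

`minimize_b2_numeric` minimizes Δρ² = ∫(ρ₁−ρ₂)²4πr²dr over B₂ by bounded
Brent search on [10⁻³B₁, 50B₁] with xatol = 10⁻⁸B₁. The objective is
evaluated through the Gaussian-overlap closed form

    Δρ² = Z₁²(2π/B₁)^{3/2} + Z₂²(2π/B₂)^{3/2} − 2Z₁Z₂(4π/(B₁+B₂))^{3/2},

which `delta_rho_sq` cross-validates against adaptive quadrature (relative
tolerance 10⁻¹⁰, absolute floor 10⁻¹², radial cutoff 18√B_max/2π, beyond
which the density is < 10⁻¹⁵ of peak; near-zero differences are compared at
the scale of the self-energy terms, since the true value 0 is reached by
cancellation). A result is flagged converged only when the
central-difference gradient at the optimum vanishes within tolerance. The
minimizer agrees with the analytic B₂ to better than 10⁻⁶ relative across
u ∈ [0.4, 1.8] × B₁ ∈ [10, 30], which is the package's independent check of
the variational algebra.

## Band-limited surrogate

`band_limited_refine` minimizes ∫₀^{s_max}(Z₁e^{−B₁s²} − Z₂e^{−B₂s²})² w(s) ds
over B₂, with w = s²ds (spherical-shell measure, the default) or uniform ds
(exposed to probe robustness of the weighting choice). All integrals reduce
to error functions, so the objective is exact and the only numerics is the
1-D search. With the shell measure and s_max unbounded, Parseval's theorem
makes the minimizer identical to the real-space model-2 value, and the
implementation reproduces it to 10⁻⁶; the uniform measure changes the
exponent (2/3 instead of 2/5) and is deliberately *not* Parseval-exact.

An empirical finding worth recording: at finite s_max the minimizer does
**not** interpolate between the model-1 and model-2 predictions. Truncation
always pushes B₂ *past* the model-2 value away from model 1 — below it for
Z₂ < Z₁, above it for Z₂ > Z₁ — approaching the analytic value
monotonically as s_max grows (converged by s_max ≈ 1 Å⁻¹ for typical B).
For severe truncation with a lighter substitute (e.g. s_max = 0.2 Å⁻¹,
u = 0.5) the objective loses its interior minimum entirely and the routine
raises rather than returning a boundary value. The toy surrogate therefore
does not, by itself, explain why equal-peak compensation tracks real
refinements better than the least-squares model; whatever causes that
preference is not captured by simple spherical band limitation.

## Curve fitting and the fractional-change statistic

`ZBCurveModel` fixes the physics parameters (model, Z₁, B₀) and estimates
the single free parameter B₁,iso by unweighted least squares
(`scipy.optimize.curve_fit`); refined B tables carry no stated
uncertainties, so weighting would be invented. The fully fixed
`evaluate()` path scores a quoted-parameter curve without estimating
anything. The fractional-change statistic fits an OLS line B = mZ + c over
a restricted window (default 8 ≤ Z ≤ 25, where the curves are nearly
linear) and reports (dB/B)/(dZ/Z) = mZ_ref/(mZ_ref + c) at Z_ref = 16, the
true scatterer — the statistic is reference-point dependent and the
sulfur Z is the natural anchor.

## Synthetic data

`generate_synthetic_table` emulates an element-substitution series at a
single site: B_iso(Z) from the chosen model plus independent homoscedastic
Gaussian noise (default σ = 0.5 Å², the scale of scatter visible in refined
substitution series), on an integer Z grid 7–34 (N through Se). Defaults
Z₁ = 16 e⁻, B₀ = 6 Å², B₁,iso = 12 Å² mirror a fully occupied sulfide site
in a well-ordered ~1.2 Å structure. What the generator does *not* emulate:
correlations between sites, resolution-dependent series termination,
solvent and lattice contributions, restraint coupling, or
occupancy/B trade-offs inside an actual refinement program. Passing the
parameter-recovery tests (bias < 0.05 Å² at σ = 0.5, n = 12, 200
replicates) therefore shows the estimator is correct *for the model's own
data*, not that real refined tables obey either model.

## Degenerate inputs and tie-breaks

Negative B₂,iso values (possible for small Z₂/Z₁ when B₀ exceeds the scaled
total) are returned as-is with a `NegativeBIsoWarning` — the analytic curve
is what the models describe; physical admissibility is the caller's call,
and the CLI surfaces the warning on stderr. Occupancy inversion returns the
raw ratio, including values > 1 (a heavier effective scatterer).
`occupancy_from_b` requires B₂,iso + B₀ > 0; outside that range there is no
solution and a `NotInvertibleError` is raised with the offending values.

## Problem sizes

Everything here is closed-form or 1-D; the heaviest computations in the
shipped tests are the 24-point oracle grid (two Brent searches per point)
and the 200-replicate recovery study (one 1-parameter curve fit per
replicate), each a few seconds on one core. Those sizes were chosen as the
smallest that pin the oracle agreement to 10⁻⁶ and the estimator bias to
the 0.05 Å² level.

## Known limitations

* Neutral atoms only: no ions, anomalous dispersion, or neutron lengths.
* Single-Gaussian substitution: the Z-independence of the atomic shape is
  assumed, so cross-element occupancy ratios are approximate.
* The electron-table edition is one of several published variants; absolute
  electron ρ(0) values are parameterization-native.
* PDB-format text only for coordinate input (isotropic B field); mmCIF and
  anisotropic ADPs are out of scope.
* The band-limited surrogate is spherically averaged and solvent-free; it
  is a caricature of refinement, useful for bracketing intuition only.
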