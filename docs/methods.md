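# Methods

## The physical model

Two coaxial parallel disc electrodes of radius *a* (default 12.5 mm, i.e.
25 mm paddles) are separated by the tissue thickness *h* (the measured
caliper distance, 4–12 mm in practice). The package computes the *nominal*
current density in the mid-plane between the discs at a total applied
current of 1 A, then scales it by the peak current recorded at each
application site. Because densities follow from current alone, no tissue
conductivity is needed or exposed; voltage-derived "field strength"
(V/cm) is computed only as a descriptive label, since electrode
polarisation makes the in-tissue gradient smaller than applied
voltage/distance.

**Uniform-source disc pair.** Each paddle is a uniform current source
(resp. sink) disc of surface density σ = I/(πa²) in an infinite
homogeneous conductor. A point source *i* contributes a radial density
*i*/(4πr²); integrating the axial component over a disc gives
σ·Ω/(4π), where Ω is the solid angle the disc subtends at the field
point. At the mid-plane both discs contribute equally:

    J_z(x) = σ · [Ω(x, h/2) + Ω(x, h/2)] / (4π) = σ · Ω(x, h/2) / (2π).

Assumptions this buys and their costs:

- *Uniform source vs ideal conductor.* Physical paddles are nearly
  equipotential, which crowds current toward the disc rim. The
  semi-analytical elliptic-integral route exists only for the
  uniform-source density, so that is the default; the finite-difference
  solver's `equipotential` mode quantifies the approximation. Measured at
  h = 7 mm, a = 12.5 mm: the equipotential centre density is ~24% *lower*
  than the uniform-source value (ratio 0.75–0.77, stable under grid
  refinement). The discrepancy is carried in the profile metadata, never
  hidden: centre-density thresholds computed with the default model are
  systematically conservative relative to an ideal-conductor reading.
- *Infinite homogeneous medium.* Tissue slab edges, neighbouring organs
  and the indifferent skin patch are ignored; the free-space Green
  function has no boundary terms. Adequate near the axis where the dose
  is read; unquantified near the tissue margins.

**Solid angle of a disc (off-axis).** On the axis,
Ω = 2π(1 − d/√(d² + a²)). Off the axis the disc solid angle reduces to
complete elliptic integrals; with r₂² = d² + (a+ρ)², m = 4aρ/r₂²,
n = 4aρ/(a+ρ)²:

    Ω = 2π·[ρ < a] − (2d/r₂) [ K(m) + ((a−ρ)/(a+ρ)) Π(n, m) ],

with the rim case ρ = a handled by its limit Ω = π − (2d/r₂)K(m).
Π is evaluated through Carlson symmetric forms (scipy `elliprf`/`elliprj`).
An adaptive-quadrature fallback — the radial integral of the point-source
kernel has a closed form, leaving one smooth azimuthal integral — agrees
with the elliptic route to better than 1e-8 relative (tested on a grid of
(ρ, d) including the rim and far field) and to ~7e-11 in practice.

**Conservation check.** The mid-plane flux ∫ J_z(x)·2πx dx must equal the
applied current. `midplane_flux` integrates the tabulated profile
(trapezoid) and closes the integral with an analytic dipole tail: beyond
the grid the disc pair looks like a current dipole of moment I·h, so the
tail carries a fraction f = h/(2·x_max) of the total. The tail estimate
is itself accurate to O((a/x_max)²) ≈ 2% *of the tail*; with the default
cap f ≤ 10%, total flux error stays well below 1%. Measured: 0.9997–0.9998
A for h ∈ {4, 7, 12} mm on a grid to 100 mm. (A grid shorter than 5·h
raises a precision error instead of returning a silently truncated flux.)

**Thickness quantisation.** `lookup` mode rounds h to the nearest whole
millimetre (ties to even) before evaluating, mirroring a 1 mm-step lookup
table; `continuous` mode (the default) uses h as measured. The 1 mm
tabulation is a bookkeeping convention, not physics.

## The finite-difference oracle

An independent numerical route used only for cross-checking: the steady
conduction problem on an axisymmetric (r, z) grid, discretised in a
conservative finite-volume form, second order in the spacing. The
potential is antisymmetric about the mid-plane, so only the upper half is
solved with V = 0 on the mid-plane; the sparse system is factorised
directly (the role a fully converged relaxation sweep would play, without
an iteration-tuning surface). Defaults: spacing a/50, domain radius 12a,
axial half-height 6a. The domain must be generous — an insulating outer
boundary at 8a compresses the dipole far field and inflates the mid-plane
density near x = 2a by ~4%, and grid refinement does not remove the bias;
at 12a the measured maximum deviation from the elliptic route is 1.3–1.5%
for x ≤ 2a, h ∈ {4, 7, 12} mm. In `uniform_source` mode the disc injects
exactly 1 A through per-cell annular areas clipped to the disc; in
`equipotential` mode the disc nodes are pinned and the profile is
post-scaled to unit mid-plane current.

## Threshold estimation

A successful ablation is a section in which non-viable parenchyma spans
the tissue between the paddles; a site is successful if any of its 2–4
sections spans.

Two per-site threshold estimators, both reported and labelled:

- **centre** (default): J_nominal(0; h) × I — the dose *delivered* at
  X = 0. Faithful to reading the density curve at the lesion centre, but
  it is a delivered-dose quantity: it equals the necrosis threshold only
  for marginal lesions, and overestimates it for comfortably successful
  sites.
- **boundary**: the scaled profile evaluated at the median necrotic
  half-width across sections — the dose at the necrosis/transition
  boundary, where delivered dose equals threshold by definition. The
  median (not mean) is used for robustness with 2–4 sections. A half-width
  of zero degenerates to the centre reading.

Per-pulse peak currents are collapsed to one value per site by averaging
(`mean`; `max` and `last` available) — with four serial pulses and one
summary current reported per group, averaging is the only combination
consistent with the published table. Sites with arcing are included by
default and excludable by flag. Group summaries are mean ± SD (n−1),
either over all sites or success-only; both filters appear in reports
because it is not recorded whether failed sites entered the published
group means.

## Synthetic cohorts

`SyntheticCohortConfig` defaults state the study-like world: 12 pigs ×
3 conditions; thickness per *site* uniform over integer mm 4–12 (the span
of the published per-group ranges); per-pulse peak currents normal with
the published per-group means/SDs (25.3±3.1, 32.4±5.4, 22.4±2.9 A),
truncated positive; peak voltages = current × a contact-resistance draw
(30±5 Ω, matching the published ~25–35 Ω); arcing with probability 1/6 in
the 100 J group only (2 of 12 such applications arced). Ground truth is a
per-pig threshold θ_ig = mean_g + u_i with a shared animal effect
u_i ~ N(0, sd_between): sharing u across the three conditions is what
makes the within-pig repeated-measures design meaningful. Group means
default to the published 4.3/5.1/3.4 A/cm² — the serial default is
equivalently the pooled single mean reduced by the published factor 1.4.
The published group SDs mix animal physiology with measurement scatter,
which summary data cannot separate; the default splits the variance
evenly, sd_between = mean(0.8, 0.9, 0.5)/√2 ≈ 0.52 A/cm².

A site succeeds iff its delivered centre density reaches θ; the true
necrotic half-width is the exact profile inversion max{x : J(x)·I ≥ θ}
(bracketed root finding, zero for failures), and each section observes it
with clipped Gaussian noise (default SD 0.5 mm — a realistic scale for
caliper/section reading error; no value is published). The transition
zone extends to where the dose falls to 75% of θ (a fixed fraction chosen
once; only the necrotic boundary feeds estimation). Draw order is
independent of the threshold parameters, so raising thresholds at a fixed
seed can only turn successes into failures (tested).

**What a green recovery test does and does not establish.** The
generator and the boundary estimator invert the same profile, so with
noiseless histology the estimator returns each successful site's θ
exactly (measured matched bias ~1e-13); recovery is therefore assessed
against the *matched truth* — the mean true θ over the sites that entered
the estimate. It cannot be assessed against the unconditional configured
mean: success censors sites whose θ exceeds the delivered dose, biasing
any estimator low by ~0.3 A/cm² at the defaults regardless of noise. A
green recovery test establishes that the estimation chain is
self-consistent and noise-robust, not that real histology reading is
unbiased, and not that the field model matches the tissue.

The synthetic world also does not reproduce the published success rates:
under the uniform-source model the delivered centre densities at the
published currents/thicknesses sit ~7–15% below the published thresholds,
so default cohorts succeed in roughly 2–5 of 12 sites per group rather
than 5/11/12. This is an honest gap between the package's field model and
whatever produced the published numbers; consequently the exact McNemar
reproduction uses the published success counts as inputs (reconstructing
the paired table under nested discordance — no pig succeeding at a weaker
setting while failing at a stronger one, the only structure consistent
with the published p-values).

## Statistics

- **Exact McNemar**: conditional on n = b + c discordant pairs, the split
  is Binomial(n, ½) under the null; p = min(1, 2·Σ_{k≤min(b,c)} C(n,k)/2ⁿ).
  Chosen over the chi-square variant because the published p-values
  (0.016, 0.031) equal the exact values (0.015625, 0.03125) for the
  nested tables. With b = c = 0 the test is uninformative and p = 1.
- **Repeated-measures ANOVA**: explicit decomposition SS_total =
  SS_conditions + SS_subjects + SS_error, F = MS_cond/MS_error on
  (k−1, (k−1)(n−1)) df. Sphericity is assumed by default (k = 3);
  `greenhouse_geisser=True` deflates both dfs by the ε estimated from the
  double-centred condition covariance (clamped to [1/(k−1), 1]). A zero
  error variance — e.g. any exactly additive subject+condition matrix —
  is a degenerate design and raises, rather than returning an infinite F.
  Simulated type-I error at α = 0.05 under exchangeable nulls:
  within [0.035, 0.065] over 2000 cohorts (tested at a fixed seed).
- **Paired contrast**: t procedure on d = x − y with t-quantile CI;
  identical differences are flagged degenerate with a point CI.
- Tests are two-sided, α = 0.05; reports round p-values to 3 decimals.

## Numerical choices

- Elliptic vs quadrature agreement enforced at 1e-8 relative; quadrature
  tolerances 1e-13 absolute / 1e-12 relative.
- Lesion-edge inversion by `brentq` on [0, 8a] (xtol 1e-10); a boundary
  beyond 8a raises rather than extrapolating.
- Flux tail cap 10% of total (see conservation above).
- Positivity truncation of random draws by clipping at 1e-3 in the
  generator's units; at the default parameters the clip is never active
  in practice but guarantees the invariant under fuzzing.
- Seeds: every stochastic path takes one integer seed; multi-cohort
  harnesses derive child seeds via `SeedSequence.generate_state` reduced
  below 2³¹.

## Known limitations

- Single-axis, coaxial, parallel paddles only; no tilt, offset or
  heterogeneous/anisotropic conductivity.
- Only the peak current of each pulse is consumed; waveform shape,
  pulse-train electro-thermal effects and damage-accumulation physics are
  out of scope (the serial-application benefit is represented only as a
  lower effective threshold).
- The equipotential-vs-uniform-source gap (~24% at the centre for the
  reference geometry) bounds the model error attributable to the
  electrode idealisation; which idealisation better matches real paddles
  on tissue is not resolvable from summary data.
- Healthy pancreas parenchyma is the reference tissue; tumour tissue has
  a different structure and likely different thresholds.
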