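# Methods

This note documents the models behind each budget term, the parameter
choices and their rationale, what the synthetic-ocean generator does and
does not emulate, and the numerical decisions that affect results.
Units follow one convention throughout: depth in metres positive
downward, nutrient concentrations in µmol m⁻³ (1 nM ≡ 1 µmol m⁻³),
tracers on grids in mmol m⁻³, and all budget fluxes in µmol N m⁻² d⁻¹.

## Thorpe-scale mixing

A gravitationally unstable patch in a CTD density profile is detected by
stably sorting potential density anomaly σ_θ into ascending order. Each
sample's **Thorpe displacement** is the depth of its sorted position
minus its own depth; a stable (mergesort) sort with index-order
tie-breaking guarantees equal densities displace by zero and that
displacements sum to zero over the full profile and over every complete
patch. Patches are maximal index runs where the running displacement sum
departs from zero and returns to zero (tolerance 1e-9 relative to the
largest displacement).

Per accepted patch:

- `L_T` = rms displacement over the patch (m);
- `N² = (g/ρ₀)·Δσ_sorted/Δz` from the endpoint difference of the sorted
  profile across the patch (a least-squares slope is selectable via
  `MixingParams.n2_method="fit"`; the endpoint form is the default
  because sub-metre patches rarely support a meaningful fit);
- `ε = (a·L_T)²·N³` with Ozmidov/Thorpe ratio `a = 0.8`;
- `K_z = Γ·ε/N² = Γ·a²·L_T²·N` with mixing efficiency `Γ = 0.2`.

`a = 0.8` and `Γ = 0.2` are the community-standard values for
overturn-based diffusivity estimates; both are configuration, not
constants, because published choices vary (`a` 0.66–1.0, `Γ` 0.15–0.2).

Quality control: patches must span ≥ 3 samples and a sorted density
range ≥ 0.002 kg m⁻³ (the noise floor of a pumped CTD at typical bin
sizes); patches with non-positive N² are rejected with a warning.
Pre-processing drops samples that do not increase pressure (package
reversals) and samples deviating from a 5-point running median by more
than 10× the noise threshold (despiking specifics for raw profiler
files are not standardized; the running-median rule is this package's
choice and both window and factor are exposed).

Per-cast `K_z` is mapped onto uniform 5-m depth bins: a bin overlapped
by patches carries their displacement-weighted mean `K_z` (weight =
patch `L_T` × overlap length); all other bins carry a background floor
of 1e-6 m² s⁻¹ — the canonical open-ocean interior value — so that the
cross-cast **geometric mean** (the right average for a log-distributed
quantity spanning decades) is defined everywhere and never reports
zero diffusivity. Layer values are geometric means over the bins inside
the layer.

## Turbulent nitrate flux

`F = K_z · d[NO₃⁻]/dz · 86400` in µmol N m⁻² d⁻¹, positive upward when
concentration increases downward (this is the classic
`F_z = −K_z·d[NO₃⁻]/dz` under a z-positive-up convention). The gradient
is the OLS slope of concentration against depth over a 20-m window
centred on the layer boundary (two samples reduce to a finite
difference; fewer than two samples inside the window pull in the
nearest bracketing samples). The 20-m default balances resolving the
nitracline's curvature against noise suppression; the exact
differencing window used in comparable field studies is rarely stated,
so it is exposed as configuration.

Boundaries used by the pipeline: 60 m (base of the upper euphotic zone,
UEZ) and 110 m (base of the euphotic zone). With a nitracline whose
onset lies at 125 m, the UEZ gradient is indistinguishable from zero
and the 110-m gradient is a few µmol m⁻⁴, giving fluxes ≪ 0.01 and
~0.1–1 µmol N m⁻² d⁻¹ respectively.

## Lateral control-volume transport

Surface POC → PON via Redfield stoichiometry (16/106 mol N per mol C),
then block-averaged to ~8 km (joint mean over all valid source cells
per block; fully masked blocks stay masked). Velocities are regridded
to the tracer grid bilinearly in space at the two bracketing time
slices and linearly in time.

The control volume is a simple lon/lat polygon with depth extent
H = 55 m; the surface tracer is taken vertically uniform over H (the
standard assumption when only surface fields exist). Cells whose
centres fall inside the polygon define the rasterized volume; every
face between an inside and an outside cell is a boundary face with

```
flux_in = −(v⃗·n̂_out) · C_edge · L_face · H
```

where `v⃗·n̂` is the mean of the two adjacent cell velocities normal to
the face, `C_edge` the mean of the two adjacent tracer cells (an
upwind/donor-cell scheme is selectable; centred is the default because
it is second-order and makes the conservation identity below exact), and
`L_face` the face length. A masked neighbour falls back to the unmasked
cell; a face with both cells masked contributes zero and is counted in
a coverage diagnostic. Net flux per area = Σ face fluxes / volume
surface area.

**Geometry.** Face lengths and cell areas default to spherical formulas
(Earth radius 6371 km) because 1/3° cells at 25° N are distinctly
anisotropic. A `"plane"` metric (uniform local tangent plane at the
mean latitude) exists for exactness tests: on that metric, a velocity
field obtained by centred differences of any streamfunction is
divergence-free *in exactly the discrete stencil of the flux operator*,
so a uniform tracer yields a net flux at roundoff (the conservation
property is checked at |net|/gross ≤ 1e-8). On the spherical metric the
same construction conserves to O(Δ²) in the metric variation — a few
parts in 1e5 for this domain — which is why the exactness tests pin the
metric rather than the tolerance.

**Eddy detection.** Local SSH extrema are candidate eddy centres. Among
closed SSH contours (level spacing 0.02 m, ≥ 4 vertices) enclosing
exactly one extremum, the one maximizing the mean along-contour current
speed is the eddy boundary; polarity follows the extremum sign
(anticyclonic for highs in the northern hemisphere). For a Gaussian SSH
anomaly of width σ the geostrophic azimuthal speed peaks exactly at
r = σ, which the tests use as an analytic oracle. The eddy share of the
lateral flux recomputes the boundary sum over only the faces whose
inside-cell centre lies within any eddy polygon.

## N₂-fixation and nitrification potential

Chl-specific fixation follows a saturating, non-photoinhibited P–I
curve `F(E) = fmax·(1 − exp(−α·E/fmax))`; volumetric rate =
trichomes L⁻¹ × 1000 × (ng chl trichome⁻¹ × 1e-3) × F(E) × photoperiod.
Dark fixation is taken as zero and the 12-h photoperiod scales the
daily integral, consistent with the culture conditions (26 °C, 12 h)
behind published coefficient sets. The default coefficients —
`fmax = 1.667e-3` µmol N (µg chl)⁻¹ h⁻¹ with saturation irradiance
`E_k = fmax/α = 100` µmol photons m⁻² s⁻¹ — are chosen so that one
trichome carrying 1 ng chl fixes 20 pmol N d⁻¹ at saturation, the
per-trichome magnitude implied by observed abundance/rate envelopes in
oligotrophic subtropical waters; any published coefficient set can be
dropped in without code changes. Depth integration is trapezoidal with
the integration bounds inserted as interpolated nodes.

Nitrification potential is literally the product of the ambient
ammonium stock and an ammonium-specific oxidation rate (0.02–0.5 d⁻¹
spans reported oligotrophic values); the function reports the exact
product and no rounding.

## Migrant active transport

Migrant biomass per size class = max(0, night − day) from paired
oblique tows; negative differences are clipped because a daytime excess
is not a migrant signal. Excretion per individual follows
`ln E = a₀ + a₁·ln m_C + a₂·T` with `m_C` the class mean individual
carbon (mg C) and `T` the residence-depth temperature (default 11 °C,
the midpoint of a 300–500-m thermocline layer); the flux is
individuals × E × hours at depth (default 12 h, daytime residence). The
coefficient set is configuration because published allometric excretion
regressions differ in mass currency and units; the defaults
(a₀ = −4.5, a₁ = 0.8, a₂ = 0.0693 ≈ ln 2/10, i.e. Q₁₀ = 2) give
weight-specific ammonium excretion of ~0.06 µmol N (mg C)⁻¹ h⁻¹ for a
0.01 mg C epipelagic copepod at 11 °C, mid-range for the literature.
Organic (DON) excretion and mortality at depth are not modelled, so the
estimate is a lower bound by construction.

## Budget synthesis

Support fraction of a source = 100 × source/export. The lateral
requirement is the non-negative residual export − Σ(local sources), and
its share closes the budget; the synthesis treats measured exports and
productions as inputs (provenance-tagged in the output table) and never
mixes them with computed terms. The f-ratio is NP/(NP+RP). ¹⁵N uptake
rates follow the standard end-point tracer equation
`ρ = PN·(A_final − A_nat)/(A_enriched − A_nat)/t` with natural
abundance 0.3663 atom %. The two-endmember δ¹⁵N balance
`f_fix = (δ_NO₃ − δ_exp)/(δ_NO₃ − δ_fix)` is clipped to [0, 1] with the
raw value retained as a diagnostic, and is monotone decreasing in
δ_export whenever δ_NO₃ > δ_fix.

## Synthetic-ocean generator

All generators are pure functions of (config, seed); per-generator
streams are split as `default_rng([stream_index, seed])` with fixed
stream indices, so adding casts never perturbs the tow noise.
Emulated study conditions (defaults):

- **Casts**: 20 casts, 0–200 m at 0.25 m, constant N² = 1.2e-4 s⁻²
  (σ_θ 23 at the surface); Poisson(1) overturns per cast at 60–100 m,
  heights 0.6–1.2 m, injected by density-reversing the segment;
  Gaussian sensor noise (SD 4e-4 kg m⁻³) well under the 0.002 kg m⁻³
  rejection threshold. Sub-metre patches are deliberate: with
  N ≈ 0.011 s⁻¹ they give patch diffusivities of order 1e-4 m² s⁻¹ and
  cast-averaged geometric means of 1e-6–1e-5, the weak-mixing decade of
  strongly stratified subtropical thermoclines. Ground-truth patch
  bounds, L_T (from a brute-force stable sort of the final noisy
  segment) and N are recorded for recovery tests.
- **Nutrients**: logistic nitracline with onset at 125 m (half-width
  6 m; the logistic midpoint sits three half-widths deeper so nitrate
  is still depressed at the onset depth), pinned to 30 µmol m⁻³ at the
  surface and 2500 µmol m⁻³ at 150 m; ammonium flat at 60 µmol m⁻³.
  The analytic profile and gradient are exposed so OLS gradients can be
  checked against closed forms.
- **Surface fields**: SSH = linear ramp (encoding a mean drift of
  (0.06, −0.03) m s⁻¹ that carries margin water into the interior) +
  three drifting Gaussian mesoscale anomalies (amplitudes ±0.15–0.25 m,
  radii 60–80 km), one of them straddling the control-volume boundary.
  Velocities are geostrophic on an f-plane by centred differences of
  SSH with the spherical metric — the discrete spherical divergence of
  such a field vanishes identically, which the generator tests verify
  at roundoff. POC = 1.5 mmol C m⁻³ offshore + 4 mmol C m⁻³ coastal
  enhancement decaying at 80 km from the west/north margins +
  eddy-trapped anomalies + lognormal noise + a 3 % cloud mask; ten
  8-day composites.
- **Biology**: trichomes 19 L⁻¹ at the surface with a 6-m e-folding
  (UEZ fixation integral ≈ 2.4 µmol N m⁻² d⁻¹), PAR 1500 × exp(−0.04 z);
  tow pair with day biomass (150…30) mg C m⁻² across the five standard
  size classes, migrant fractions 0.1–0.4, giving active transport of
  ~50 µmol N m⁻² d⁻¹.
- **Measured inputs**: UEZ/LEZ exports 980/520 µmol N m⁻² d⁻¹, UEZ new
  and regenerated production 700/9300 (f = 0.07), δ¹⁵N endmembers
  2.9‰ (nitrate), −1‰ (fixation), 2.9‰ (export).

What the generator does **not** emulate: time-evolving dynamics (each
composite is an independently drawn snapshot, so the lateral flux
series understates real autocorrelation); ageostrophic and wind-driven
currents; vertical structure in the surface tracer (uniform over H);
β-plane effects; patchy trichome blooms; and swimmer contamination or
trap hydrodynamics in the "measured" exports, which are clean inputs
here. Passing tests therefore demonstrate the correctness of the
estimators and bookkeeping under the documented statistical structure,
not the realism of any particular magnitude — with one deliberate
exception: the magnitude ordering (local sources ≪ export, hence a
dominant lateral requirement) is a designed-in property of the study
conditions.

## Numerical choices and degenerate inputs

- Stable sorts everywhere displacement order matters; ties displace
  zero.
- Patch-span tolerance 1e-9 (relative) on the cumulative displacement;
  an unclosed patch at the profile end is closed at the last sample.
- Geometric means computed in log space; zero or negative diffusivities
  are rejected rather than silently floored.
- Percentiles use linear interpolation of order statistics.
- The control volume must not touch the grid edge (face neighbours
  would be undefined); that is an error, not a fallback.
- Longitudes are rewrapped to −180…180 and axes forced ascending on
  read; NetCDF I/O uses the NetCDF-3 (scipy) backend with CF-style
  (time, lat, lon) dimensions and mandatory units attributes.
- Seeds are 31-bit non-negative integers; every random stream descends
  from the single master seed.

## Problem sizes

The default configuration — 20 casts × 801 samples, 160-m flux
profiles on 5-m bins, a 66 × 120 tracer grid × 10 composites, 3 eddies —
runs the full pipeline in a few seconds on one core; the test suite's
largest property checks (1000 random sort-oracle profiles, 100
recovery casts) complete in seconds. These sizes were chosen to be the
smallest at which every statistical property under test is stable.

## Known limitations

- The Thorpe method reports a noise floor, not zero, where no overturn
  is resolved; true diffusivities below 1e-6 m² s⁻¹ are not
  distinguishable.
- Centred edge concentrations can produce small negative tracer fluxes
  near sharp masked boundaries; the upwind option trades that for
  first-order diffusion.
- Eddy attribution assigns whole boundary faces by cell-centre
  membership; faces partially inside an eddy are not split.
- The budget's lateral term is a residual; it inherits every bias of
  the measured export and of the (deliberately excluded) DON and
  mortality pathways.
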