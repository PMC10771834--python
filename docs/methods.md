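# Methods

This note records the models, conventions and numerical choices behind
`aneumorph`, and what the synthetic validation does and does not show.

## Scope and inputs

The pipeline starts downstream of segmentation and CFD. Its inputs are
(1) a triangulated sac surface, open along the neck, in millimetres;
(2) a neck annotation — plane point, unit normal oriented toward the dome,
and an ordered closed contour lying in the plane — supplied as a JSON
sidecar rather than detected automatically (no robust neck-detection rule
exists that we would be willing to validate silently); (3) a parent-vessel
centerline with local radii, ordered proximal → distal; and (4) optionally
a per-vertex WSS vector time series over one cardiac cycle. Units are mm
and Pa throughout; readers never rescale, and coordinates are a plain
right-handed frame (no imaging-orientation handling).

Loaded meshes are cleaned deterministically: vertices merged within
1e-9 mm, zero-area faces dropped, closed surfaces re-oriented so the signed
volume is positive.

## Morphometric conventions

Several printed quantities have more than one defensible definition; the
choices here are:

- **Hmax** — distance from the neck-contour centroid to the farthest sac
  vertex (ties broken by lowest vertex index). **H** — largest signed
  distance to the neck plane.
- **Dmiddle** — the sac is cut by `n_slices` planes parallel to the neck
  plane, evenly spaced over (0, H); each intersection contour contributes
  its maximum in-plane chord, and the neck contour itself competes. The
  default `n_slices = 100` changes by < 1 % against 1000-slice brute force
  on bumpy fixtures (tested).
- **Dneck** — by default the maximum in-plane chord of the contour
  (`max_width`); an area-equivalent diameter 2·√(A/π) is available because
  clinical tools are not consistent on this convention.
- **Dvessel** — twice the mean centerline radius within a window of the
  closest-approach point to the neck centroid; the default window is one
  local vessel diameter. The averaging window is a convention, hence a
  parameter.
- **V, S** — the open sac is closed by a triangle fan from the boundary
  centroid, wound consistently with the sac faces (a cap wound the wrong
  way corrupts the divergence-theorem volume once the geometry leaves the
  origin — this is enforced structurally, not by sign luck), and V is the
  signed volume of that closed surface. S excludes the cap. **Vch, Sch** —
  convex hull of sac + contour vertices; hull facets lying in the neck
  plane (vertices within 1e-6 mm) are excluded from Sch.
- **Indices** — UI = 1 − V/Vch, EI = 1 − (18π)^{1/3}Vch^{2/3}/Sch,
  NSI = 1 − (18π)^{1/3}V^{2/3}/S. The (18π)^{1/3} constant makes all three
  vanish for a hemisphere precisely because S and Sch exclude the neck cap;
  recomputing NSI from the bundled measured (V, S) pairs reproduces the
  reported values to 3 decimals (the fourth only to ±0.001, limited by the
  3-dp rounding of its inputs).
- **Angles** — the sac main axis runs from the neck centroid to the
  farthest vertex. θA is the angle between that axis and the *proximal
  in-plane direction* (the negated projection of the proximal→distal flow
  tangent onto the neck plane): 90° means perpendicular to the plane,
  values above 90° lean downstream. θF is the angle between the axis and
  the *proximal vessel direction* at the closest-approach point. Both use
  the proximal reference; this is the only reading consistent with
  downstream-leaning aneurysms reporting θF and θA above 90°, but
  published tools do not state their convention, so recorded angles from
  other software may need the 180°−θ complement. Both are reported in
  [0, 180]° and are null without a centerline.

## Hemodynamic definitions

TAWSS, OSI and RRT use the standard cycle-average definitions (trapezoidal
quadrature on possibly non-uniform grids; no periodic-spline option).
RRT = 1/((1−2·OSI)·TAWSS) equals 1/|time-mean WSS vector| algebraically;
the implementation computes the formula and the test suite checks the
identity to 1e-9, which guards both the quadrature and the OSI definition.
Degenerate cases: a vertex with identically zero WSS gets OSI = 0 with a
warning; RRT is capped at 1e6 1/Pa where the mean vector vanishes
(OSI → 0.5). Sac summaries are area-weighted vertex means (weight = one
third of incident triangle areas, exact for linear fields); an unweighted
mean is available since "average" is ambiguous in clinical reports. NWSS
divides the sac mean TAWSS by the mean over a user-supplied parent-artery
field; the normalization region is the user's choice (the same near-neck
window convention as Dvessel is recommended). RRT is reported in 1/Pa;
published values are sometimes nondimensionalized, which is an unresolved
ambiguity when comparing magnitudes.

A multi-cycle series can be reduced with `select_cycle`, matching the
practice of discarding start-up transients and keeping the final simulated
cycle.

## Risk scoring

Threshold flags are strict inequalities against literature cutoffs shipped
in `data/thresholds.json` (θF > 118.25°, θA > 96.1°, AR > 1.6, SR > 1.75,
UI > 0.09, EI > 0.13, NSI > 0.16, NWSS < 0.39, OSI > 0.0036, RRT > 2.7,
RRS > 30 %). The three logistic models use feature sets M:{SR},
H:{NWSS, OSI}, C:{SR, NWSS, OSI}; each term may be log-transformed (the
transform field exists because published hemodynamic models are typically
fit on log(OSI)/log(WSS), but the exact published transforms are not
recoverable here). **The shipped coefficient file is synthetic**: the
originally published slope/intercept blocks were not available to this
implementation, so `data/rrs_coefficients_synthetic.json` carries
illustrative values with the correct sign structure only. Absolute RRS
percentages from the defaults are therefore not clinically meaningful;
the scoring machinery (transforms, strict 30 % rule, monotonicity) is what
is validated. Users supply their own coefficients, or refit via
`risk.fit_logistic` (plain maximum-likelihood logistic regression through
statsmodels) on a labelled table.

## Synthetic data and ground truth

The generator emulates the measured study conditions — sacs with
Hmax ≈ 3–8 mm and Dneck ≈ 5–7.5 mm on parent vessels of 3–4.3 mm diameter,
optionally undulated or carrying a daughter bleb, over a 1 s cardiac cycle
(60 bpm) sampled at 200 points with mean WSS of order 1 Pa.

A sac is the image of the upper unit hemisphere under
N = Shear·diag(a,b,c) on a lat-long grid (refinement level ℓ gives a
4·2^ℓ × 2^ℓ grid; the default ℓ = 5, ~8k faces, puts hemisphere V and S
within 0.1 % of closed form; ℓ = 3 is used where only topology matters).
The shear preserves z and volume, so H = c and V = ⅔πabc exactly. The
farthest surface point of the sheared ellipsoid is *not* the apex: it is
the top singular direction of N, so Hmax and the axis direction (hence θA)
are computed analytically from the 2×2 eigenproblem of the x–z block of
NNᵀ, and `SacSpec.from_targets` inverts that relation in closed form so
that requested (Hmax, Dneck, Dvessel, θA, θF) are the exact ground truths.
θF is realized by dipping the straight centerline by γ = θF − θA (feasible
for |γ| < 89°). Degenerate axes (hemispheres) claim no angle truth.
Undulation is a radial cosine ripple and the daughter sac a Gaussian bleb,
both pinned to zero at the neck ring and the ripple also at the apex; with
bumps present only the Dneck/Dvessel/H truths are retained. Parameter
recovery uses refinement 6, where the azimuthal/elevation quantization of
the farthest-vertex axis stays below ~0.5°, comfortably inside the 1°
validation band.

WSS fields are analytic, not flow solutions: per-vertex
τ(t) = (m + A sin(2πt/T + φ))·d along a fixed tangent d. The cycle
averages are closed-form (TAWSS = m and OSI = 0 for m ≥ A; otherwise with
α = arcsin(m/A), TAWSS = (2/π)(A cos α + m α) and OSI = ½(1 − m/TAWSS)),
which is exactly what the validation needs — known OSI/TAWSS — and
deliberately not physiological: no Womersley profiles, no spatial
correlation, no secondary-flow structure. Passing these tests shows the
*postprocessing* is correct, not that any CFD upstream is.

Volume oracles are independent of the divergence-theorem path: V by
bounding-box rejection sampling with a vectorised +z ray-parity test
(triangles bucketed on a 64×64 planar grid), Vch by rejection against the
hull's half-space inequalities, both with binomial standard errors.
Cross-checks run at 10⁶ samples and 3σ.

## Determinism and reporting

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical config and inputs give
byte-identical reports, and every CLI run logs the package version, a
SHA-256 config hash and all settings to stderr. Reports print lengths and
indices to 3 decimals, OSI to 4 (its cutoff is 0.0036), and RRS as
percentages to 2 — the precisions at which these panels are conventionally
reported.

## Known limitations

- No neck detection, centerline extraction, segmentation or flow solving.
- Binary STL/PLY round-trips are float32-limited (~1e-6 relative); use
  OBJ/VTP (full double precision) when exact round-trips matter.
- The angle conventions (proximal reference) and the Dneck/Dvessel
  averaging windows are documented choices, not community standards;
  cross-tool comparisons should verify conventions first.
- Default RRS coefficients are illustrative placeholders (above).
- The synthetic geometries are star-shaped single-lobe sacs; heavily
  multi-lobed or tortuous-neck anatomies are untested territory for the
  slicing and hull conventions.
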