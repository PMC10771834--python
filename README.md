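# aneumorph

Morphometry, wall-shear-stress postprocessing and rupture-resemblance
scoring for saccular intracranial aneurysms.

Whether an unruptured intracranial aneurysm warrants intervention is still
largely decided by its size, yet small aneurysms do rupture. Shape and
hemodynamics carry much of the missing signal: how tall the sac is relative
to its parent artery, how far it departs from a smooth dome, and how
strongly the wall shear stress (WSS) on it weakens and oscillates over the
cardiac cycle. `aneumorph` computes this panel reproducibly from an
already-segmented sac surface — it does not segment images and it does not
solve blood flow; it consumes a triangulated sac with a neck-plane
annotation, a parent-vessel centerline, and (optionally) a per-vertex WSS
vector time series exported from a CFD solution.

## What it computes

**Morphology** (lengths in mm, from the sac mesh, neck contour and
centerline): maximum height `Hmax` (neck centroid to farthest point),
perpendicular height `H`, maximal cross-section `Dmiddle`, neck diameter
`Dneck`, local parent-artery diameter `Dvessel`, sac volume `V` and area
`S`, convex-hull volume `Vch` and (neck-free) area `Sch`, and the angles
θF (sac axis vs proximal vessel direction) and θA (sac axis vs proximal
in-plane direction). Derived indices:

    AR  = H / Dneck                          aspect ratio
    SR  = Hmax / Dvessel                     size ratio
    UI  = 1 − V / Vch                        undulation index
    EI  = 1 − (18π)^(1/3) Vch^(2/3) / Sch    ellipticity index
    NSI = 1 − (18π)^(1/3) V^(2/3) / S        non-sphericity index

All three indices are zero for a hemispherical sac (the neck cap is excluded
from `S` and `Sch`) and grow with lobulation and elongation.

**Hemodynamics** (from the WSS series τ_w(t), trapezoidal quadrature over
the cycle):

    TAWSS = (1/T) ∫ |τ_w| dt
    OSI   = ½ (1 − |∫ τ_w dt| / ∫ |τ_w| dt)            ∈ [0, 0.5]
    RRT   = 1 / ((1 − 2·OSI)·TAWSS) = 1 / |mean τ_w|
    NWSS  = sac-averaged TAWSS / parent-artery TAWSS

**Risk scoring**: every parameter is flagged against a literature cutoff
(e.g. SR > 1.75, OSI > 0.0036, NWSS < 0.39), and three logistic
rupture-resemblance scores RRS_M (SR), RRS_H (NWSS, OSI) and RRS_C (all
three) are reported with a strict 30 % decision rule. The shipped
coefficient file is synthetic/illustrative (see `docs/methods.md`); supply
a validated coefficient JSON or refit one with `risk.fit_logistic`.

A first-class synthetic-data module generates sac-on-vessel geometries and
pulsatile WSS fields with *known* ground truth (closed-form heights, angles,
volumes, TAWSS and OSI), plus Monte-Carlo volume oracles, so every stage is
testable without patient data.

## Worked example

Generate a synthetic fixture bundle (surface, annotation sidecar, WSS
series, ground truth) and run the full pipeline:

```bash
aneumorph synth --out-dir demo --seed 1
aneumorph full --surface demo/sac.stl --annotation demo/annotation.json \
    --manifest demo/wss/wss_manifest.txt \
    --parent-manifest demo/wss_parent/wss_manifest.txt \
    --out-dir demo/out
```

`demo/out/report.csv` then contains (seed 1):

```
parameter,value,unit,threshold,flag
Hmax,5.999,mm,/,/
H,5.841,mm,/,/
Dmiddle,5.8,mm,/,/
Dneck,5.8,mm,/,/
Dvessel,3.5,mm,/,/
V,102.787,mm^3,/,/
S,91.574,mm^2,/,/
thetaF,125.589,deg,>118.25,yes
thetaA,105.589,deg,>96.1,yes
AR,1.007,,>1.6,no
SR,1.714,,>1.75,no
UI,0.0,,>0.09,no
EI,0.08,,>0.13,no
NSI,0.08,,>0.16,no
NWSS,0.588,,<0.39,no
OSI,0.0749,,>0.0036,yes
RRT,1.25,1/Pa,>2.7,no
RRS_M,44.29,%,>30,yes
RRS_H,84.38,%,>30,yes
RRS_C,89.43,%,>30,yes
```

The fixture was built with target Hmax = 6 mm, Dneck = 5.8 mm,
Dvessel = 3.5 mm, θA = 105°, θF = 125° (see `demo/truth.json`): the measured
panel recovers them to mesh resolution. The smooth ellipsoidal sac has
UI = 0 (it is convex), its SR of 1.714 sits just under the 1.75 cutoff, and
the synthetic WSS field's oscillation produces the flagged OSI. RRS rows use
the illustrative default coefficients.

The same panel is available in Python:

```python
from aneumorph import synthetic, morphometry
geom = synthetic.make_sac(synthetic.SacSpec.from_targets(
    hmax=6.0, dneck=5.8, dvessel=3.5, theta_a_deg=105, theta_f_deg=125))
result = morphometry.compute_all(geom)
print(result.SR, result.NSI)
```

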