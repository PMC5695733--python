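# stromakit

Quantitative morphometry of the corneal stroma, built for studies that
compare fibrillin-1–deficient (Marfan-model) and wild-type mouse corneas.
The package implements three measurement pipelines plus the synthetic
phantoms and statistics needed to validate them end to end without any
instrument data:

1. **OCT corneal geometry** — central corneal thickness and anterior radius
   of curvature from spectral-domain OCT volumes.
2. **SAXS collagen spacing** — calibrated interfibrillar Bragg spacing (IFS)
   and axial D-period from 2D small-angle x-ray scattering patterns.
3. **Elastic-fiber volumetrics** — depth-resolved volume fractions and fiber
   diameters from serial block-face SEM stacks.

## The measurements

**OCT geometry.** Raw OCT depths are optical-path pixels; below the anterior
surface the in-air axial scale is reduced by the tissue refractive index, so
a span of *p* pixels converts to physical thickness

> t = p · s / n

with *s* the axial scale in air (μm/px) and *n* = 1.4 for mouse cornea.
The anterior radius of curvature comes from the sagitta construction: on the
traced anterior surface an arc of fixed height *h* = 300 μm is taken at the
apex, its chord width *w* measured, and Pythagoras applied to the
half-chord/apothem triangle:

> R = w² / (8h) + h / 2

**SAXS spacing.** Each detector image is azimuthally averaged about the beam
center into I(q), with the exact mapping q = (4π/λ)·sin(θ),
2θ = arctan(r·pitch/L). The q-scale is calibrated empirically against the
67 nm meridional D-period of hydrated rat tail tendon (beam centering uses
silver behenate-style powder rings), a power-law background A·q^(−b) is
fitted in log–log space and subtracted, and the interfibrillar spacing is
the Bragg spacing of the first-order equatorial reflection:

> d = 2π / q_peak

**Fiber volumetrics.** A grayscale SBF-SEM stack is thresholded (Otsu or
fixed), small components are removed, a total-least-squares reference plane
is fitted to Descemet's-membrane markers (blocks are rarely cut parallel to
the surface), and voxels are binned by signed distance above that plane in
12.5 μm bins — the equivalent of 250 serial sections at 50 nm. Per bin the
elastic-fiber volume fraction is 100 × fiber voxels / total voxels; fiber
diameters are measured as twice the median distance-transform radius along
each component's medial axis.

Every pipeline has a matching phantom generator (`stromakit.synth`) that
emits ground truth alongside the data, so parameter recovery is testable to
known tolerances.

## Worked example

```python
from stromakit import synth, oct

truth = synth.OCTPhantomTruth(radius_mm=1.94, thickness_um=183.6, seed=1)
volume = synth.gen_oct_volume(truth)           # speckled spherical cap
geom = oct.measure_cornea(volume)              # average, trace, measure
print(f"thickness {geom.thickness_um:.1f} um, "
      f"radius {geom.radius_mm:.3f} mm, chord {geom.chord_width_um:.0f} um")
```

prints

```
thickness 183.7 um, radius 1.939 mm, chord 2072 um
```

i.e. the phantom's 183.6 μm wild-type-like thickness and 1.94 mm radius are
recovered to 0.1 μm and 0.05% through the full chain (frame averaging,
surface tracing, refractive-index correction, sagitta geometry), with
speckle noise on. The same round trip is available from the shell:

```sh
stromakit simulate --kind oct --seed 4 --out sim/
stromakit oct-measure --input sim/oct_phantom --out measured/
```

Each run writes its fully resolved configuration and a log next to its
outputs; identical config + seed gives byte-identical outputs.

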