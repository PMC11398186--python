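# rhizocurl

Quantification of root-hair curling and nodule development for in-situ
(microrhizotron) imaging of legume–rhizobia symbiosis.

Root hairs are the initial infection site of the symbiosis: after
inoculation they deform and curl, and nodules later swell from the root
axis. Both processes happen in soil, observed through a small buried
imaging window, which leaves two measurement problems once a segmentation
mask of the root tissue is in hand:

1. **Root hairs cross and overlap** in projection, so individual hairs must
   be separated before their curling can be quantified. `rhizocurl` thins
   the mask to a one-pixel skeleton (classic two-subiteration Zhang–Suen),
   prunes spurs, bridges small gaps, and traces each hair from its axis
   attachment to its tip. At junctions the continuation with the smallest
   tangent-direction change is taken, bounded by a positional rule: at most
   30° mid-hair (hairs grow smoothly, with no sudden break point), at most
   80° in the tip zone, where genuine curling concentrates.
2. **The imaging window only sees ~1 mm into the soil**, so a nodule wider
   than the visible depth *L* shows only a chord *d* of its cross-section.
   The real diameter of the buried sphere is recovered as

   D = (4L² + d²) / (4L),

   the inverse of the chord of a sphere sectioned at depth L,
   d = 2·√(L·(D − L)).

On top of these sit the curling angle β — the direction change between the
tangent at the hair's midpoint (points Pᵢ, Pⱼ, 5 px apart) and the tangent
at its tip (Pₖ, Pₗ), β = arccos(PᵢPⱼ·PₖPₗ / (|PᵢPⱼ||PₖPₗ|)), extended past
the arccos's 180° cap by accumulating signed tangent increments so that
tight curls (up to ~268°) are measured correctly — a hair with β > 90° is
classified as curled — and ordinary least-squares dose–response fits of
nodulation traits on log₁₀ rhizobia density.

A synthetic-scene generator renders calibrated masks with exact ground
truth (axis, hairs of prescribed total turning, the four canonical
crossing patterns, buried-sphere nodule caps), so every stage is testable
without real images.

## Worked example

`examples/01_measure_curling.py` renders one axis with five hairs of known
total turning, runs the full pipeline, and prints:

```
hair  true turn   measured beta   curled?
   0         45            45.0   False
   1         90            89.6   False
   2        180           180.7   True
   3        268           267.7   True
   4          0             0.0   False

group mean beta = 116.6 deg (SD 107.7), curled fraction = 0.40
```

Each measured β is the recovered curling angle of one separated hair;
hairs with β strictly over 90° count as curled (uninfected hairs are wavy
but stay below ~45°, so 90° separates rhizobia-induced curling from
baseline waviness). `examples/02_nodule_diameter.py` converts observed
nodule diameters and closes the loop on a rendered nodule:

```
rendered nodule: true D = 5.33 mm, expected chord = 4.16 mm
measured observed d = 4.16 mm -> real D = 5.33 mm
```

`examples/03_dose_response.py` fits nodule and curled-hair counts against
log₁₀ inoculant density, and `examples/04_separate_crossing_hairs.py`
shows crossing-hair separation in isolation.

There is also a thin CLI over the same functions:

```
rhizocurl run mask.png --mm-per-pixel 0.01 --visible-depth 1.0 --out-dir out/
rhizocurl skeletonize --in mask.png --out skel.png
rhizocurl simulate --out-dir sim/ --turning 0,120,268
```

`run` writes per-mask CSVs (hairs, curl measurements, nodules) plus a JSON
manifest with the configuration echo and row counts.

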