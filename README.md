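# brachykernel

A deterministic point-kernel dose engine for intracavitary brachytherapy
(ICBT) treatment verification.  Most planning systems superpose
water-medium dose-rate tables per source and ignore the applicator itself;
`brachykernel` computes dose rates around encapsulated Cs-137 / Ir-192
sources *including* the heterogeneities — source capsules, steel
applicator tubes, tungsten sector shields — by ray tracing every
source-to-detector chord through a combinatorial solid geometry.

It is aimed at medical physicists who want fast, independent second checks
of gynecological ICBT plans (Manchester-system tandem-and-ovoid loadings,
shielded vaginal cylinders) without running Monte Carlo transport.

## Model

A line source is discretized into point emitters (Δl = 0.05 mm by
default).  For each emitter and spectrum line E_i the dose rate is the
attenuated inverse-square kernel times a buildup factor, converted to
collision kerma in water:

    Ḋ(r) = Σ_i R_i E_i · B(μ|r−r'|, E_i) · exp(−Σ_j μ_j s_j) / (4π|r−r'|²)
           · (μ_en/ρ)_w(E_i) · 1.602·10⁻¹³ · 10³ · 3600   [Gy/h]

Scatter is handled by geometric-progression (GP) buildup factors
B(x) = 1 + (b−1)(K^x−1)/(K−1), and layered paths (capsule → tissue,
capsule → shield → tissue) are composed with the two-region rule that
selects its branch by the effective atomic numbers of the layers.  Source
strengths may be stated as air-kerma strength S_k, linear reference
air-kerma rate, or activity.  See `docs/methods.md` for the full model,
data provenance and reconstruction assumptions.

Shipped applicator builders: the BRIT LDR tandem-and-ovoids (CSA-1/CSA-2
Cs-137 train), the Fletcher Green type LDR applicator (CDC-J Cs-137), the
Fletcher–Williamson HDR applicator (stepping mHDR Ir-192, 20 dwells), and
a shielded vaginal cylinder with 90/180/270° tungsten sectors.

## Worked example

Write the example plan files and evaluate the standard BRIT loading
(long straight tandem, ovoids at 3 cm separation, 1.5 cm below the os),
sources only, with the per-source breakdown:

```sh
brachykernel fixtures plans/
brachykernel compute-points plans/brit_sources_only.yaml --per-source
```

```text
# reference-point dose rates (cGy/h)
point	x_cm	y_cm	z_cm	S1	S2	S3	S4	S5	dose_rate	unit
A_right	2	2	0	26.7024	45.8217	53.3717	19.8139	9.90564	155.615	cGy/h
A_left	-2	2	0	26.7024	45.8217	53.3717	9.90564	19.8139	155.615	cGy/h
B_right	5	2	0	10.363	9.17708	9.47176	9.9306	4.29318	43.2357	cGy/h
B_left	-5	2	0	10.363	9.17708	9.47176	4.29318	9.9306	43.2357	cGy/h
```

Rows are the Manchester reference points (cm, in the tandem frame);
S1–S3 are the tandem sources from the fundus down (350/230/230
μGy·h⁻¹·m²), S4/S5 the right/left ovoid sources (230 each).  Point A
receives ~156 cGy/h, dominated by the lower tandem sources; the left/right
mirror symmetry of the loading is exact.  Re-running with
`plans/brit_standard.yaml` (walls on) lowers point A by ~1.7% — the
attenuation of the 0.5 mm steel tube walls, partly offset by their
scatter buildup.

The same library surface is available from Python:

```python
import brachykernel as bk

lib = bk.build_standard_library()
geom, sources, points = bk.build_brit_ldr(lib, with_walls=False)
model = bk.DoseModel(geom, sources, lib, delta_l=0.005)
print(model.point_dose(points["A_right"]))   # 155.6 cGy/h
```

`brachykernel compute-grid` writes 3D dose lattices, `brachykernel
isodose` extracts marching-squares isodose polylines (percent of a
normalization point, e.g. 100%/200% at point A, or absolute cGy/h
levels), and a `profile` block in a vaginal-cylinder plan produces the
0–180° angular dose table around the shield.

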