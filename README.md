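# glucocest

Simulation and analysis of **glucoCEST MRI**: chemical exchange saturation
transfer (CEST) imaging of D-glucose and its non-metabolizable analog
3-O-methyl-D-glucose (3OMG) in phantoms and tumor-bearing animals.

CEST detects millimolar sugar concentrations through their hydroxyl
protons: selective radio-frequency saturation 1–3 ppm downfield of water
is transferred to the bulk water signal by chemical exchange, attenuating
it measurably. Scanning the saturation offset yields a *Z-spectrum*
`Z(Δω) = S(Δω)/S0`, and the contrast metric is the asymmetry

    ST = (S(−Δω) − S(+Δω)) / S0 ,      Δω = 1.2 ppm,  S0 = S(−10 ppm)

which cancels the symmetric direct water saturation. Dynamic studies
report `ΔST% = (ST_post − ST_pre) × 100` after agent injection, the
fraction of tumor pixels with ΔST% > 0, and test contrast changes over
time with one-way ANOVA plus Dunnett comparisons against the first
post-injection time point.

The package is aimed at researchers developing or validating CEST
processing: it pairs a multi-pool **Bloch–McConnell simulator** (phantoms
at controlled pH, dynamic two-compartment tumor uptake, B0 fieldmaps,
noise — all with ground truth) with the full **voxel-wise analysis
chain** (threshold segmentation, smoothing-spline interpolation, B0
correction via the bulk-water minimum, asymmetry ST maps with an
R² > 0.97 quality filter, ΔST% dynamics and group statistics), so every
analysis step can be checked against known truth.

## Worked example

```python
import glucocest as gc

acq = gc.AcquisitionConfig(B0=7.0, offsets=tuple(gc.make_offset_list(0.1, 10.0)))
sat = gc.SaturationScheme(B1=3.0, duration=5.0)
water = gc.water_preset(7.0, "solution")

for ph in (7.4, 7.0, 6.4, 6.0):
    z = gc.simulate_zspectrum(gc.glucose(), 20.0, ph, water, sat, acq)
    print(f"pH {ph}: glucose ST = {100 * z.asymmetry(1.2):.1f}%")
```

prints

```
pH 7.4: glucose ST = 1.7%
pH 7.0: glucose ST = 9.3%
pH 6.4: glucose ST = 28.7%
pH 6.0: glucose ST = 32.1%
```

— 20 mM glucose at 7 T / 3 μT develops strong saturation transfer only at
acidic pH, because hydroxyl exchange slows toward the labeling-efficiency
optimum as pH drops. Running the same sweep for `gc.omg3()` peaks near
pH 7.0 instead: the two agents' opposite pH preferences are what make the
glucose/3OMG comparison interesting for probing tumor acidification.

The `examples/` directory contains one narrative script per capability
(spectrum simulation, phantom ST mapping, dynamic contrast, group
statistics); each prints the numbers it computes and what they mean. A
thin CLI mirrors the pipeline:

```sh
glucocest run --config cfg.yaml          # simulate -> process -> analyze
glucocest process st --input stack.nii.gz --analysis-offset 1.2 --r2 0.97
```

Stacks are NIfTI volumes (rows × cols × offsets) with a plain-text
offsets sidecar; maps, tables and statistics are written as NIfTI, CSV
and JSON. See `docs/methods.md` for the spin model, the exchange-rate
presets, the smoothing and centring conventions, and known limitations.

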