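# pillchroma

Smartphone photos of solid medications are a tempting input for automated
pill identification, but the colour a camera records depends heavily on the
scene: background colour, flash, and exposure compensation (EV) all shift a
pill's apparent colour away from the catalogue reference it must be matched
against. `pillchroma` is a desk-scale workbench for quantifying that effect.
It is aimed at researchers studying imaging-condition robustness of
recognition systems who need a fully controlled, ground-truthed test bed
rather than a physical photo rig.

The workbench covers the whole study design end to end:

1. **Synthesis** — render a 19-class pill catalogue (7 shapes, 7 colour
   categories, 4 dosage forms) under a reference condition (black
   background, flash off, EV 0) and a 2×2×3 factorial of real-world
   conditions: background ∈ {black, white} × flash ∈ {on, off} ×
   EV ∈ {−2.0, 0, +2.0}. Every frame carries its ground-truth mask and
   surface colour.
2. **Segmentation** — isolate the pill with a classic chain: grayscale →
   Gaussian blur → Otsu threshold → Canny edges → contour closing and fill →
   bitwise mask → square crop, with a documented threshold-mask fallback and
   loud failures on hopeless frames (e.g. white pill, white background,
   overexposed).
3. **Colorimetry** — mean ROI colour → XYZ → CIE L\*a\*b\* → colour
   difference against the reference condition,

   ΔE\*ab = √(ΔL\*² + Δa\*² + Δb\*²),

   with L\* = 116·f(Y/Yn) − 16, a\* = 500·(f(X/Xn) − f(Y/Yn)),
   b\* = 200·(f(Y/Yn) − f(Z/Zn)), where f(q) = q^⅓ above 0.008856 and
   7.787·q + 16/116 below. The reference white is anchored to the RGB→XYZ
   matrix so L\* spans exactly [0, 100] on the in-gamut cube.
4. **Recognition** — an interpretable surrogate classifier (mean Lab colour
   + scale-invariant shape descriptors + imprint score, nearest class mean)
   evaluated as top-1/top-5 accuracy per condition.
5. **Statistics** — per-condition ΔE mean±SD over the 19 medications, a
   three-way repeated-measures ANOVA (medication as subject), stratified
   one-way RM-ANOVA over EV per background×flash stratum with
   Bonferroni-adjusted paired comparisons, and the Spearman association
   between condition ΔE and recognition accuracy.

## Worked example

```python
import pillchroma as pc

cfg = pc.ExperimentConfig(seed=0, n_per_cell=2)   # 19 pills × 13 sets × 2
bundle = pc.run_experiment(cfg)
print(bundle.condition_table[["condition", "top1", "top5",
                              "mean_delta_e", "sd_delta_e"]].round(3))
print(bundle.association["spearman"])
```

prints (seed 0):

```
 condition  top1  top5  mean_delta_e  sd_delta_e
B_O_EV-2.0 0.237 0.789        35.051       4.585
   B_O_EV0 0.789 1.000         9.992       3.967
B_O_EV+2.0 0.237 0.789        34.771      21.231
W_O_EV-2.0 0.237 0.658        41.182       5.569
   W_O_EV0 0.184 0.684         7.042       4.131
W_O_EV+2.0 0.000 0.105        31.522      17.972
B_X_EV-2.0 0.263 0.842        39.972       3.740
   B_X_EV0 0.947 1.000         0.138       0.194
B_X_EV+2.0 0.342 0.737        29.849      17.654
W_X_EV-2.0 0.263 0.763        46.039       4.356
   W_X_EV0 0.684 0.974         8.880       1.035
W_X_EV+2.0 0.105 0.316        26.980      16.287

{1: -0.275, 5: -0.295}
```

Reading this: each row is one real-world condition (`B`/`W` background,
`O`/`X` flash on/off, EV in stops). ΔE is the colour distance between a
pill's mean ROI colour under that condition and under the reference
condition, averaged over the 19 medications (±SD). Conditions close to the
reference (`B_X_EV0` — same scene, new noise and pose) show near-zero ΔE
and the highest top-1 accuracy; under- and over-exposed or white-background
conditions push ΔE up and accuracy down. The negative Spearman coefficients
summarise the inverse relation between colour shift and accuracy.
`bundle.anova_three_way` holds the F table (background, EV and all
interactions significant here; flash alone not), and
`pc.write_report(bundle, "out/")` renders the two-panel accuracy/ΔE figure
and a markdown summary.

The same pipeline is scriptable from a shell:

```
pillchroma run --config experiment.yaml
pillchroma generate --out data/ --seed 0
pillchroma segment --in data/manifest.csv --out rois/
pillchroma colordiff --manifest data/manifest.csv --rois rois/ --out delta_e.csv
```

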