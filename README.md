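# acidoquant

Quantitative pipelines for the cell biology of the proton-activated chloride
channel PACC1/TMEM206 and its splice isoforms (V1, which retains exon 2, and
the canonical V2): transcript abundance from single-molecule in situ
hybridization images, nuclei-seeded cell segmentation, colocalization with
organelle markers, absolute endosomal pH from ratiometric flow cytometry,
plasma-membrane channel activity from halide-sensitive YFP (HS-YFP) quench
kinetics, and acid-induced cell-death scoring. It is written for imaging and
physiology labs that want these procedures as tested, scriptable code rather
than point-and-click analysis modules.

Because assays of this kind rarely ship raw data, the package includes
first-class synthetic-data generators for every input — tissue fields of
nucleated cells with known per-cell transcript counts, correlated two-channel
images, dual-transferrin cytometry event tables, 14-s quench plates, and
Hoechst/propidium-iodide viability fields — each with recorded ground truth,
so every pipeline is validated end to end by recovery experiments.

## The core quantities

**eDots (estimated dots).** Each mRNA appears as an amplified punctum of unit
area A₀ (6 µm²). Per-cell abundance is

    eDots = (supra-threshold signal area within the cell) / A₀

which stays accurate when dots fuse into clusters — the regime where counting
connected components collapses. Rounded eDots drive positivity (≥ 1 dot),
marker-based cell classification (≥ 10 dots), and expression bins
(1–9 / 10–30 / >30).

**Endosomal pH.** The median FITC/AF633 transferrin ratio of
reporter-gated events is inverted through a 4-point standard curve
(pH 7.4 / 6.5 / 5.5 / 4.5), interpolated piecewise-linearly in log-ratio.

**Quench kinetics.** Post-injection HS-YFP decay is fitted with
F(t) = plateau + A·e^(−kt); the rate is |dF/dt| at injection, and its pH
dependence follows rate(pH) = rate_max / (1 + 10^(n·(pH − pH50))), giving the
half-maximal activation pH (pH50) and maximal activity (rate_max).

**Death fraction.** PI-positive nuclei over all Hoechst nuclei, with a
plate-pooled two-class threshold on per-nucleus mean PI intensity.

## Worked example

Simulate a quench plate and extract the pH dependence:

```bash
$ acidoquant simulate traces --out run/ --seed 7
$ acidoquant quench --traces run/traces.csv --layout run/layout.csv \
      --background 100 --out run/fit
pH50 5.50, hill_n 1.88, rate_max 0.229
```

The generator's truth for this plate is pH50 5.5, Hill coefficient 2 and
maximal rate 0.23 normalized units/s — the fit recovers the half-activation
pH exactly and the maximal rate within 0.5%. Per-well rates are in
`run/fit/rates.csv`, the Hill parameters with standard errors in
`run/fit/hill.json`.

The same pattern works for the other assays, e.g.

```bash
$ acidoquant simulate tissue --out field/ --seed 3
$ acidoquant segment --image field/field.tif --nuclear-threshold 0.5 --out seg/
200 nuclei, 187 cells retained
$ acidoquant spots --image field/field.tif --seg seg/ --signal-threshold 0.5 --out spots/
187 cells, fraction positive 0.866
```

(13 of the 200 simulated cells touch the field border and are removed, per
the segmentation contract; the cohort was generated with 85% positive cells.)

Every `simulate` run writes a `manifest.json`; `acidoquant rerun --manifest
... --out ...` reproduces all outputs bit-identically.

The numbered scripts under `analysis/` run the full studies — tissue
expression profiling, cell-type co-expression, colocalization, endosomal pH
across parental/knockout/rescue conditions, isoform quench kinetics, and the
acid-death dose response — printing their findings and writing tables under
`results/`.

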