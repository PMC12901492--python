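# Methods

`acidoquant` implements the quantitative procedures used to characterize the
proton-activated chloride channel PACC1/TMEM206 and its splice isoforms:
per-cell transcript quantification from fluorescent in situ hybridization
(RNAscope) images, nuclei-seeded cell segmentation, colocalization metrics,
ratiometric endosomal pH from dual-transferrin flow cytometry, HS-YFP quench
kinetics with a Hill pH-dependence, and acid-induced death scoring. No raw
data accompany the package; every pipeline is exercised on synthetic data
whose generators are first-class, tested code with recorded ground truth.
This note documents the models, the defaults and why, the numerical choices,
and what the synthetic data do and do not establish.

## Transcript quantification (eDots)

Each mRNA appears as an amplified fluorescent punctum of known unit area
(6 µm² by default). Per-cell abundance is estimated as

    eDots = (supra-threshold signal area inside the cell) / unit dot area,

rather than by counting connected components, because fused clusters in
high-expressing cells merge many dots into one component. For area-based
counting the key requirement is *count additivity*: the supra-threshold area
of n dots should be n times the unit area even when dots abut. Connected
components smaller than the minimum dot size are discarded first; because a
unit dot's pixelated area fluctuates with sub-pixel position (21–26 px for a
24 px dot at 0.5 µm/pixel), the minimum-size comparison allows a margin of
ceil(equivalent dot radius in pixels) — without it, true unit dots would sit
on the filter's knife edge and ~30% would be lost.

Rounded eDots (`eDots_int`, round half up) feed every integer "dots" rule:
positivity (≥ 1), marker classification (≥ 10), and the expression bins
1–9 / 10–30 / >30. Cells reaching the marker threshold in more than one
marker channel are left unclassified with the reason recorded.

### Dot model in the generator

Dots are rendered as unit-amplitude flat-top disks convolved with a Gaussian
PSF (`dot_psf_sigma_um`), the disk radius calibrated so the half-maximum
contour encloses exactly `dot_area_um2`; intensities of overlapping dots add.
A pure Gaussian of the same half-max area is *not* an adequate model for a
6 µm² amplified spot: it would be ~25× wider than the diffraction limit and
carry half its energy outside the half-max contour, producing a long-range
intra-cell glow that shifts any absolute threshold and destroys count
additivity. The PSF width (default 0.65 µm) was calibrated so that the area
statistic is count-additive on non-clustered fields (|bias| < 4% across
1–60 dots/cell): with much sharper edges, partially overlapping dots lose
their lens-shaped intersection (−13% at 30 dots/cell); with much softer
edges, summed tails re-create the glow. In other words the generator is tuned
to emulate imaging conditions under which area-based counting demonstrably
works — the regime the method was designed for — and the clustering stress
test then probes its failure modes.

Clustered placement puts a new dot *adjacent* to an existing one (centre
offset uniform in 0.5–1 dot diameters), so clusters fuse laterally. A
concentric stack would be invisible to any area measure and is implausible
for a thin optical section.

### Tissue geometry and expression defaults

Cells are modelled as nucleus-seeded territories: all pixels nearer (Euclidean
distance to the nucleus mask) to a nucleus than to any other, out to a uniform
growth distance. Defaults: nucleus radius 4.0 ± 0.4 µm, cell radius 12 µm
(sd 0 — a single growth radius matches the single `max_radius_um` the
segmentation uses), pixel size 0.5 µm (confocal-scale; configurable), dot
amplitude 1.0 on background 0.1 with Gaussian noise sd 0.02. The 12 µm soma
is cortical-scale and is also the smallest size that can geometrically
accommodate the high-expression class: >30 dots of 6 µm² occupy >180 µm²,
more than an 8 µm cell's entire cross-section.

Per-cell counts for positive cells follow a zero-truncated negative binomial
with mean 7 and dispersion 0.8, whose bin mix (0.690 / 0.283 / 0.027 across
1–9 / 10–30 / >30) matches the reported astrocyte fractions
(70.21 / 26.77 / 3.01%) and whose mean of 8.4 dots per positive cell lies in
the 4–30 range reported across tissues; the default positive fraction is
0.85 (cerebrum-like). These are the study conditions for all cohort-level
recovery experiments.

## Segmentation

Background subtraction is a morphological opening (disk footprint, decomposed
for speed) of a 3×3 mean-filtered copy — mean-filtering first, as rolling-ball
implementations do, stops the opening from tracking noise minima — plus
removal of the residual pedestal (the median of the subtracted image; valid
while background pixels are the majority). Nuclei are connected components
(4-connectivity throughout) of the thresholded nuclear channel (Otsu by
default, fixed override in all simulation studies where the amplitude is a
known physical constant), filtered by a 10 µm² minimum area. No declumping is
attempted: one touching blob is one label.

Cell growth assigns each admissible pixel (guide intensity ≥ floor, or inside
a nucleus) to its nearest nucleus if within `max_radius_um`; Euclidean
distance to the nucleus mask stands in for geodesic distance and coincides
with it whenever the admissible region is locally convex around each nucleus
(always true at the default floor of 0). Pixels not 4-connected to their
nucleus are dropped when a positive floor can disconnect regions. Ties at
equidistant pixels follow the distance transform's deterministic
nearest-index rule. Any region touching the image border is deleted and its
label recorded. µm-valued parameters convert to pixels by rounding half up;
areas are reported as pixel counts × pixel area.

On simulated fields the analysis growth radius is set to the generator's
(cell − nucleus) radius, so retained-cell counts are exactly recoverable;
with per-cell radius variation (supported, sd > 0) recovery becomes
approximate.

### Per-cell background floor

`quantify_spots` optionally raises each cell's threshold by the cell's
off-dot intensity floor (default: the 20th percentile of background-subtracted
intensities in the cell region, clamped at ≥ 0 by the non-negative image).
On the default generator this floor is ~0 and the correction is inert; it
exists for data whose high expressors carry diffuse cytoplasmic signal.

## Colocalization

`pearson_above_threshold` correlates two channels over pixels where at least
one channel exceeds its threshold (union rule; switchable to intersection —
the reference plugin's rule is version-dependent). Thresholds are fixed
values or a Costes-style bisection that walks thresholds down the orthogonal
regression line until sub-threshold pixels are uncorrelated (|r| ≤ 1e-3).
Fewer than 10 qualifying pixels, or zero variance among them, is an error,
not a number. `overlap_fraction` thresholds both channels to masks, drops
marker components below a minimum structure area, and reports
area(marker ∩ signal)/area(marker).

The generator builds the two test beds independently inside one object:
correlated Gaussian fields (exact population correlation, mean 1000, sd 100 —
10 sd above zero, so clipping never engages) and a punctate marker/signal
mask pair in which an exact fraction of equal-sized (integer-centred, hence
identical) marker disks lies wholly inside the signal mask. With this
construction no (ρ, overlap) combination is infeasible.

## Endosomal pH

Events carry FITC (pH-sensitive) and AF633 (pH-insensitive) transferrin
intensities plus an mCherry transfection reporter. Gating keeps events above
the 99th percentile of an untransfected control's reporter distribution.
Per-event ratios exclude events with AF633 below 1% of the sample median
(ratio blow-up guard); the central ratio is the median (robust to the
lognormal tails), and the generator's multiplicative noise is median-centred
so the central ratio is noise-invariant by construction.

The standard curve maps the median ratio at each calibration buffer pH
(7.4 / 6.5 / 5.5 / 4.5) and must be strictly monotone. Inverse interpolation
is piecewise-linear in **log10 ratio** vs pH: for a logistic probe response
(pKa 6.4 default), log-ratio is nearly linear in pH below the pKa, so
log-space interpolation tracks the response closely (max analytic error
~0.08 pH at pH 5.9 on the 4-point curve), whereas raw-ratio interpolation is
convex between nodes and biased by up to ~0.19 pH at pH 5.3. Plain-linear and
4-parameter sigmoid inversions are available. Ratios outside the calibrated
range clamp to the nearest node with a flag. Interpolating a calibration
sample's own central ratio returns its nominal pH exactly under any monotone
transform of the axis.

Untransfected events in experimental samples carry their own (more acidic,
default 4.7) pH, so reporter gating has a measurable effect.

## Quench kinetics

Raw traces (14 s at 0.2 s, injection at 2 s; instrument scale 1000, offset
100) are background-subtracted and normalized to the pre-injection mean
(exactly 1 afterwards). The post-injection decay is fitted with
F(t) = plateau + A·exp(−k(t−t₀)) over a 10 s window starting at the
injection; the reported rate is |dF/dt| evaluated at the injection time from
the fitted curve (extrapolated when the window starts later), so the window
convention cannot bias the rate. Numerical choices: log-linear regression
seeds k; five seeded jittered restarts; k capped at 1/median(Δt) (a faster
"decay" would complete between samples and is unidentifiable); the
exponential is accepted over a constant only when an F-test on the nested
models rejects at p < 0.001, and boundary-k fits are treated as no-decay —
together these make flat (neutral-pH) wells report rate 0 instead of
noise-chasing artefacts. Noiseless self-fits recover (k, rate) to numerical
precision for wells with initial slope ≥ 0.01/s; slower wells (≤ 2% total
decay in-window) are a degenerate three-parameter valley where k is not
identifiable, though their rate error stays below 2 × 10⁻⁶ — they fall under
the flat-trace contract instead.

The pH dependence is rate(pH) = rate_max / (1 + 10^(n·(pH − pH50))), a
base-10 logistic in pH (equivalent to a Hill function of [H⁺]), fitted by
least squares on per-pH mean rates; inverse-variance weights are used only
with ≥ 5 replicates per point (3-replicate variance estimates make unstable
weights). In the dose-response study replicate traces are averaged pointwise
before rate extraction — equivalent to a joint common-parameter fit. Default
generator conditions: pH grid (7.5, 6.5, 6.0, 5.8, 5.5, 5.2, 4.8, 4.2)
spanning the transition into saturation, pH50 5.5, n 2, rate_max 0.23
normalized/s, plateau fraction 0.15, trace noise sd 0.02 (0.05 in the noisy
recovery study).

Isoform comparison reports per-parameter differences with combined standard
errors and a two-tailed Student's t-test on replicate rates at the most
acidic shared pH. The power study draws replicate rates at 0.23 vs 0.17 with
replicate-level sds 0.03 and 0.02 and n = 12 per group.

## Death scoring

Nuclei detected on Hoechst; each nucleus's mean PI intensity classifies it
against a threshold — fixed, or an Otsu split over per-nucleus means that
should be computed from values *pooled across a plate* so both live and dead
classes are represented (an all-live field would force Otsu to split a
unimodal distribution). Defaults: PI-positive level 0.6 ± 0.1 vs negative
0.05 ± 0.02 (validated separable at ≥ 2 sd), 100–250 nuclei per field.
Calibration across true death probabilities 0–1 (1,000 nuclei per point)
yields slope ≈ 1 and intercept ≈ 0; condition contrasts use per-field death
fractions as replicates.

## Statistics

Kolmogorov–Smirnov normality screening per group (against a normal with the
sample mean/sd; with estimated parameters the p-value is approximate, which
is why a failed screen only flags the group — the parametric test still
runs). Two groups: two-tailed Student's t (identical samples report t = 0,
p = 1). More: one-way ANOVA with Tukey's HSD post hoc (scipy's
implementation). SEM is sd/√n over replicates. No multiple-testing
correction beyond Tukey is applied.

## Problem sizes and reproducibility

Recovery experiments use cohorts of 2,000 cells (fields of 200 cells at
896² px), 10,000 cytometry events per sample with 50 Monte-Carlo repeats,
50-seed quench and death studies, and 1,000 null simulations for the ANOVA
calibration — sizes chosen to keep each experiment's Monte-Carlo error well
below the property being asserted. Every generator draws from a single
`numpy` Generator seeded per call; identical (config, seed) reproduce outputs
bit-identically, and CLI simulate runs write a manifest from which
`acidoquant rerun` regenerates all files byte-for-byte.

## What the synthetic data do not show

The generators emulate statistical structure, not optics: no z-dependence,
spectral bleed-through, autofluorescence, uneven illumination or
cell-morphology diversity (territories are truncated disks). Passing
recovery tests therefore demonstrates that the *procedures* are implemented
correctly and are robust to the modelled noise, clustering, fusion and
gating effects — not that they would meet the same error bounds on real
tissue, where segmentation error and background structure dominate. The
count-additivity calibration of the dot PSF means the cluster-robustness
result quantifies the counting-vs-area contrast under favourable optics; the
absolute biases on real data depend on the true spot profile.
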