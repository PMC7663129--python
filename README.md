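# copmat

Center-of-pressure (COP) excursion analysis for pressure-sensitive walkway
mats, with the statistics needed to judge whether a gait measurement is
reliable enough to use.

## The problem

During the stance phase of walking, the COP — the centroid of the vertical
plantar pressure distribution — travels from the heel to the toes. How it
travels (when the midfoot loads, when the heel lifts, how far and how fast
the COP sweeps mediolaterally and anteroposteriorly) characterises gait and
foot function. Instrumented walkway mats record this as time-stamped grids
of activated pressure cells (typically 240 Hz sampling, 1.27 cm cell
pitch), capturing many consecutive footfalls of both feet in one pass.
`copmat` turns those raw cell grids into per-footfall COP parameters and
quantifies, for a cohort of subjects each contributing repeated footfalls,
how reliable each parameter is and how many footfalls must be averaged for
a trustworthy measurement.

## The method

Per footfall:

1. **Segmentation** — active cells are clustered into footfalls by spatial
   8-connectivity and temporal contiguity.
2. **Foot frame** — the cells are split into proximal/middle/distal thirds
   along the foot's long axis; the heel center *H* and toe center *T* are
   the centroids of the outer thirds; with θ_c the signed angle between the
   mat's axis of progression and the line *H→T*, every raw COP sample
   (a, b) maps to foot coordinates

   ```
   (x, y) = R(θ_c) · (a − e, b − f),    H = (e, f)
   ```

   so +y points heel→toe and +x medial→lateral (x is mirrored for left
   feet).
3. **Stance events** — first contact FCT; midfoot-on MON (first activation
   in the middle third); foot-flat FFT (78% of the footfall's sensors
   activated); heel-off HOT (last deactivation in the proximal third);
   midfoot-off MOF (last deactivation in the middle third); last contact
   LCT. These bound the subphases ICP, LCP, FFP, IPP, LPP (and CbP =
   LCP+FFP); all times are normalised to % of stance.
4. **Parameters** — per subphase: duration (%), ML/AP displacement ranges
   (mm), mean COP locations (signed % of foot width/length), and ML/AP/total
   velocities (path length over duration, cm/s). The COP of a frame is the
   pressure-weighted centroid of the footfall's active cells.

Per cohort (subjects × k repeated footfalls, dominant foot):

- **ICC(2,1)** and **ICC(2,k)** — two-way random-effects, absolute-agreement
  intraclass correlations from the unreplicated two-way ANOVA, with F-based
  95% CIs; ICC(2,k) obeys the Spearman–Brown prophecy
  R_k = kR / (1 + (k−1)R), whose inversion k = R_k(1−R)/(R(1−R_k)) gives
  the number of footfalls needed to reach a target reliability.
- **CV%**, **SEM = SD·√(1−ICC(2,k))** and **MDC = SEM·√2·1.64** (90%
  confidence) for absolute reliability.

A static-footprint **arch index** (middle-third contact area of the
toe-excluded footprint over its total area) classifies foot arches, and a
**synthetic rollover generator** produces seeded mat recordings with exact
ground truth so the whole pipeline is testable without hardware.

## A worked example

```bash
python examples/03_required_footfalls.py
```

prints

```
least reliable parameters (single footfall):
category subphase   condition  icc21  required
 rangeML      ICP comfortable   0.13         7
 rangeML      ICP        fast   0.17         5
 rangeML      FFP comfortable   0.23         4

footfalls required so every parameter reaches R_k >= 0.50: 7
check: prophesied 7-footfall ICC for ICP duration = 0.963 (published 0.96)
```

The mediolateral COP range during initial contact is the least repeatable
parameter (single-footfall ICC 0.13); inverting the Spearman–Brown formula
at the customary cut-off R_k = 0.50 shows that averaging **seven
footfalls** brings every COP parameter to an acceptable reliability —
which is why a seven-footfall protocol is recommended for this
measurement. The other examples simulate a full walking trial
(`01_simulate_and_analyze.py`), build a cohort reliability report with
ICC/CV/SEM/MDC columns (`02_reliability_report.py`) and compute an arch
index from a footprint (`04_arch_index.py`).

A thin CLI wraps the same library functions:

```bash
copmat synth recording --seed 1 --out rec.csv --truth truth.json
copmat analyze --recording rec.csv --out out/ --subject S1
copmat reliability --params cohort.csv --out report.csv --k 7 --r-target 0.5
copmat arch --footprint footprint.csv
```

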