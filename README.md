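# plumemix

Quantifying riverine versus oceanic control on coastal phytoplankton from
hydrography and lipid biomarkers.

In river-influenced marginal seas — the motivating system is the Zhejiang
coast of the East China Sea — surface water is a mixture of three water
masses: nutrient-rich, turbid river plume water (Changjiang Diluted Water,
CDW), warm oligotrophic strait water (Taiwan Strait Water, TSW), and cool,
phosphate-rich upwelled subsurface water (Kuroshio Subsurface Water, KSSW).
`plumemix` turns per-station temperature/salinity, nutrient and
lipid-biomarker measurements into a quantitative account of how the water
masses structure phytoplankton biomass, community composition and lipid
export.

## The model

**Water-mass unmixing.** Each end-member *i* has characteristic
temperature and salinity (mean ± SD). Conservation of heat and salt gives

```
f₁ + f₂ + f₃ = 1,   Σᵢ fᵢ·Tᵢ = T_obs,   Σᵢ fᵢ·Sᵢ = S_obs,
```

so the fractions `f = (f_CDW, f_TSW, f_KSSW)` are the barycentric
coordinates of the observation in the end-member triangle on the T–S
plane. `solve_exact` inverts this linear system; `solve_bayesian`
samples the posterior of `f` on the probability simplex (flat
Dirichlet(1,1,1) prior, Gaussian observation error on T and S,
Gaussian end-member uncertainty marginalized in closed form) with a
random-walk Metropolis chain, reporting posterior means, SDs and a
Gelman–Rubin convergence flag. Stations outside the triangle (beyond a
configurable tolerance) are excluded with a logged reason.

**Preformed nutrients.** Conservative mixing predicts the nutrients a
station *would* have absent biology: `NOx_init = Σ fᵢ·NOxᵢ`,
`DIP_init = Σ fᵢ·DIPᵢ`. Measured-minus-preformed anomalies separate
biological uptake (negative) from remineralization (positive). Measured
DIP below the detection limit (0.02 µmol L⁻¹) is floored at
0.01 µmol L⁻¹ before N/P ratios are formed.

**Community metrics.** ∑PB = brassicasterol + dinosterol + C37
alkenones (ng L⁻¹) proxies total phytoplankton biomass; each biomarker's
share of ∑PB (B/∑PB, D/∑PB, A/∑PB) proxies the diatom, dinoflagellate
and haptophyte contributions.

**Subregions.** Stations are classified from their fractions with fixed
precedence TSWR → C-KMR → CDWR → KSSWR: TSW-dominated (f_TSW ≥ 55%),
the CDW–KSSW mixing window (40% ≤ f_CDW ≤ 90% and 5% ≤ f_KSSW ≤ 15%),
CDW-dominated (f_CDW > 40%, f_KSSW ≤ 10%) and KSSW-dominated
(f_CDW < 90%, f_KSSW > 5%).

**Statistics.** Fraction–response relationships are fitted with both a
line and a quadratic; the quadratic is kept only when it wins on both
the overall-F *p* value and the df-adjusted RMSE. Subregion contrasts
use Kruskal–Wallis with Shapiro–Wilk/Levene pre-tests; nutrient
model-vs-measurement agreement uses Spearman rank correlation; the
multivariate biomarker response is summarized by redundancy analysis
(RDA).

**Export flux.** Lipid input flux is concentration × group sinking rate
(0.95 m day⁻¹ diatoms, 0.37 m day⁻¹ dinoflagellates), converted with
k = 0.365 (kg km⁻² a⁻¹ per ng L⁻¹ · m day⁻¹).

A synthetic cruise generator (`plumemix.synthetic_data`) produces
station tables with the statistical structure above and a ground-truth
table, so the whole pipeline is testable offline with parameter-recovery
scoring.

## Worked example

```bash
plumemix simulate --scenario spring --n 60 --seed 1 --out cruise.csv
plumemix run --stations cruise.csv --season spring --seed 1 --out demo
```

writes `demo/results.csv` (one annotated row per station) and
`demo/report.json`. For this seed the report contains, among other
things:

```
subregion   n    mean ∑PB (ng/L)   mean lipid flux (kg km⁻² a⁻¹)
TSWR       10        142                  32.1
CDWR       24        410                  83.9
C_KMR      18       1990                 420.6
KSSWR       8        643                 139.3
```

The mixing subregion (C-KMR) carries by far the highest biomass and
export flux — the biomass peak sits where river nitrogen meets upwelled
phosphorus. The brassicasterol-share regression selects the linear
model with slope 0.44 (95% CI 0.23–0.64) per unit KSSW fraction: a
rise of the upwelled fraction from 0 to 40% raises the diatom share by
roughly 20 percentage points, while preformed and measured NOx
correlate at Spearman ρ = 0.97. The RDA ranks salinity and the CDW
fraction as the leading hydrographic drivers of the biomarker field.

Station tables are plain CSV (see `plumemix.io_config` for the column
schema); end-member sets are YAML/JSON, with spring and summer surface
sets bundled.

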