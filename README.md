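# hybridcline

Analysis of a **moving avian hybrid zone** from unevenly sampled museum
specimens.

In the Cauca valley of southwestern Colombia, a scarlet-rumped and a
yellow-rumped form of the flame-rumped tanager (*Ramphocelus flammigerus*)
meet along a ~135 km transect and hybridize, producing smooth geographic
gradients — clines — in body size and rump coloration. Museum skins
collected over more than a century (pre-1911, 1956–1986, 2007–2010) make it
possible to ask whether the zone has **moved** and **narrowed** over time.
But historical specimens were collected opportunistically, not at repeated
sampling sites, so classical population-genetic cline software (HZAR,
Analyse, ClineFit) cannot be used. This package implements the alternative:
dose-response **Hill functions** fitted to individual specimens scattered
along the transect.

## The model

Each trait *y* (a PCA body-size score, or spectral chroma) is modelled as a
four-parameter log-logistic function of transect distance *x*:

```
y(x) = C + (D − C) / (1 + exp(B·(log x − log E)))
```

- `C`, `D` — trait plateaus at the two ends of the zone,
- `B` — steepness (sign gives orientation),
- `E` — inflection distance.

**Cline center** = ED50 = `E`; **cline width** = ED90 − ED10 =
`E·(9^(1/|B|) − 9^(−1/|B|))`, the stretch of transect containing all
intermediate phenotypes. Uncertainty comes from a case-resampling bootstrap
(individuals resampled with replacement at constant n; replicates retained
only when the refitted center falls inside 0–140 km), and periods are
compared by ANOVA/Tukey over bootstrap replicates — a deliberate
pseudo-replication inherited from the study design and labelled as such in
every report.

Around the core regression the package provides the full pipeline:

| stage | module |
|---|---|
| specimen CSV validation, transect fit (lat-on-lon OLS), projection, sectors/localities/periods | `hybridcline.specimens` |
| per-sex correlation-matrix PCA; segment-classification brightness/chroma/hue from reflectance spectra | `hybridcline.phenotypes` |
| Hill cline fitting (`HillCline`, an sklearn-style regressor) | `hybridcline.cline` |
| filtered bootstrap, ANOVA/Tukey period comparisons | `hybridcline.uncertainty` |
| three-level AMOVA (sectors / localities / individuals) of mtDNA haplotypes with permutation P-values | `hybridcline.popgen` |
| neutral-diffusion expected cline widths (`w = σ·√(2πT)`) | `hybridcline.diffusion` |
| synthetic specimen/spectra/sequence generator with known ground truth | `hybridcline.simulate` |
| orchestration + CLI | `hybridcline.pipeline`, `hybridcline.cli` |

The original specimen measurements are not available in machine-readable
form, so the simulator is a first-class citizen: it generates specimen
tables, reflectance spectra and haplotype alignments whose statistical
structure matches the study system (cline centers near 68/74/77 km, widths
of tens of km, structured 1956 vs unstructured 2010 haplotype frequencies),
and every analysis stage is validated against that known truth.

## Worked example

```bash
hybridcline run-all --out results --seed 1
```

runs simulate → transect → phenotypes → clines → bootstrap → comparisons →
AMOVA → diffusion and writes CSV/JSON bundles. From `fits.json` and
`comparison.json` (seed 1, 300 bootstrap replicates):

```
chroma  P1911  center 72.07 km   width 27.07 km   (300 replicates retained)
chroma  P1956  center 72.40 km   width 27.05 km
chroma  P2010  center 75.67 km   width  5.13 km
```

The generating truth for these periods put the chroma cline centers at
72.92, 73.04 and 76.33 km — the fitted centers land within ~1 km, and the
eastward shift of the recent period is flagged by the Tukey comparison
(P1911 vs P2010 P < 1e-12 on bootstrap replicates). `amova.json` shows the
simulated historical structure and its recent erosion:

```
P1956  F_CT  0.136   P = 0.015    (sector-structured haplotype frequencies)
P2010  F_CT -0.000   P = 0.342    (homogeneous frequencies)
```

and `diffusion.json` reports that every fitted width (5–27 km) is far below
the neutral-diffusion envelope (≥ 137 km for dispersal 1–20 km/generation,
generation time 1–2 y, ≥ 6000 y since contact) — the signature of a tension
zone maintained by selection rather than free diffusion.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline on the default simulated world from scratch. All
quantitative acceptance checks for this artifact are property-based (exact
parameter recovery, effective-dose closed forms against root-finders,
bootstrap coverage, AMOVA permutation calibration, determinism) and live in
`tests/test_acceptance.py`.
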