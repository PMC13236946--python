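# dentale

A weighted radiographic scoring system for late dental and maxillofacial
adverse effects on orthopantomograms (OPGs) of childhood-cancer survivors,
together with its referral decision rule and the statistics used to
validate it. The tool scores human-read findings — never pixels.

## What it does

- **Scoring** — per-tooth findings for the 28 permanent teeth (FDI
  notation, third molars excluded), per-sextant findings (alveolar bone
  reduction, tooth wear), and bilateral condyle/ramus findings are combined
  into a weighted total: missing canine 8, missing incisor 6, missing
  premolar/molar 4, one point per flagged tooth aspect (crown, root,
  crown-root ratio ≥ 1:1, non-age-appropriate eruption), one point per
  sextant for alveolar reduction and for wear, 3 per abnormal condyle,
  1 per abnormal ramus. Base score range: 0–158.
- **Localized-pathology adjustment** — if any single sextant accumulates
  strictly more than 10 points, 5 points are added once (the final total
  can therefore exceed 158).
- **Referral rule** — final total ≥ 16 (inclusive, configurable) flags the
  survivor for specialized dental care.
- **Validation statistics** — two-way random-effects absolute-agreement
  ICC(2,1) with McGraw–Wong F-based 95% CIs for interobserver reliability;
  sensitivity/specificity/PPV/NPV with Wilson intervals; a threshold sweep
  implementing the safety-first selection rule (largest candidate threshold
  still achieving sensitivity 1).
- **Synthetic cohorts** — a latent-severity logistic generative model with
  a single-sextant localization mixture and configurable rater noise, so
  every statistic is testable without real radiographs.

## CLI

```sh
# generate a synthetic cohort plus a sidecar truth file
dentale simulate --seed 42 --n 83 --out cohort.json --truth-out truth.csv

# score it (JSON or CSV input; weights overridable via TOML/JSON)
dentale score --in cohort.json --out scores.csv [--weights weights.toml] \
              [--threshold 16] [--per-sextant-bonus]

# diagnostic accuracy of the referral rule over candidate thresholds
dentale validate --scores scores.csv --labels labels.csv \
                 --thresholds 14,16,18,20 --out report.json

# interobserver reliability of a subjects x raters score matrix
dentale icc --matrix matrix.csv --model icc2_1
```

Assessment files are JSON (canonical, nested per tooth) or a flat CSV
dialect with a fixed column order (`subject_id, rater_id,
age_at_opg_years, t11_status, t11_crown, …, s1_alveolar, s1_wear, …,
condyle_L, condyle_R, ramus_L, ramus_R`); booleans are 0/1, tooth status is
`present`/`missing`.

## Layout

- `src/dentale/model.py` — FDI chart, sextant map, finding types, weight
  configuration, validation
- `src/dentale/scoring.py` — score breakdown, adjustment, referral decision
- `src/dentale/validation.py` — ICC, diagnostic accuracy, threshold sweep
- `src/dentale/synthetic.py` — cohort generator, rater-noise simulator,
  recovery experiment
- `src/dentale/io.py`, `src/dentale/cli.py` — schemas, reports, CLI
- `src/dentale/eruption.py` — advisory eruption-age reference table (never
  used by the scorer)
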