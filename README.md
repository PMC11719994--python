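# ncscreen

Virtual screening of food-derived natural compounds against disease-related
protein targets. `ncscreen` implements a complete desk-scale screening
pipeline for prioritizing dietary small molecules as therapeutic candidates
(for example against Alzheimer's-disease targets such as AChE, BACE1 or
MAPT): QSAR potency regression, applicability-domain filtering, similarity
matching to known actives, cluster/SAR profiling, rule-based blood–brain-
barrier (BBB) scoring, and food-source set analysis.

It is aimed at computational chemists and food-science researchers who have
ligand-activity tables (compound, SMILES, target, IC50) and candidate
natural-compound tables, and want a reproducible screen without a deep-
learning stack.

## What it computes

**QSAR potency model.** Activities are converted to
pIC50 = −log₁₀(IC50 × 10⁻⁹) (IC50 in nM) and regressed on binary circular
(Morgan) fingerprints (radius 2, 2048 bits by default) with a random forest,
one model per target, 80:20 train/test split and k-fold cross-validation.

**Applicability domain.** Training ligands are filtered in two stages:
a potency floor (pIC50 ≥ 5), then exclusion of records whose absolute
prediction residual exceeds the 95th percentile of the absolute residuals
(linear-interpolation quantile). Predictions are only made inside this
domain.

**Similarity matching.** A candidate is flagged as potentially bioactive for
a target when the cosine similarity between its fingerprint and any of the
target's retained actives is strictly above 0.5.

**Profiling.** Hit candidates get predicted pIC50s, are clustered by k-means
on standardized descriptors plus predicted potency (k chosen by silhouette,
SSE elbow reported), and are stratified into potency tiers
(low: pIC50 ≤ 5, medium: 5 < pIC50 ≤ 7, high: pIC50 > 7) with per-tier
maximum common substructures and functional-group profiles.

**BBB score.** Each candidate is scored against five CNS drug-likeness
criteria — MW ≤ 400 Da, −0.5 ≤ LogP ≤ 5, H-bond donors ≤ 3, acceptors ≤ 7,
TPSA ≤ 90 Å² — at 20% per criterion.

**Sources.** Hits are aggregated by food source, sources ranked by hit
count, and exact Venn-region counts computed for up to six sources.

## Worked example

```python
from ncscreen.bbb import score_compound
from ncscreen.fixtures import REFERENCE_COMPOUNDS

for name in ("coumarin", "quercetin", "dihydromyricetin"):
    res = score_compound(REFERENCE_COMPOUNDS[name], compound_id=name)
    print(name, res.score_percent)
```

prints

```
coumarin 100
quercetin 60
dihydromyricetin 40
```

Coumarin passes all five criteria (MW 146.1, LogP 1.79, 0 donors,
2 acceptors, TPSA 30.2 Å²) and is predicted readily BBB-permeant; quercetin
fails the donor (5 > 3) and TPSA (131.4 > 90 Å²) criteria; dihydromyricetin
additionally fails the acceptor criterion (8 > 7).

The full pipeline runs from the command line on synthetic tables with a
planted structure–activity signal:

```bash
ncscreen make-fixtures --n 150 --seed 7 --out fixtures/
ncscreen run-all --activities fixtures/activities.csv \
                 --candidates fixtures/candidates.csv --seed 7 --out run/
```

`run/manifest.json` records the config hash, the seed, and per-stage counts
(e.g. 150 activities in, 89 ligands retained by the domain filter, 135
candidate hits, their cluster count and potency-tier breakdown), alongside
`hits.csv`, `potency.csv`, `clusters.csv`, `sar_summary.csv`, `bbb.csv` and
`top_sources.csv`.

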