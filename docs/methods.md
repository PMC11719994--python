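# Methods

## Activity model

Activity observations are IC50 values in nM, transformed to
pIC50 = −log₁₀(IC50 × 10⁻⁹). The transform is strictly decreasing and exactly
invertible (IC50 = 10^(9 − pIC50)); both directions are exposed and the
round trip is tested to 1e−6 relative error.

Potency regression uses a random forest on binary circular (Morgan)
fingerprints. The fingerprint family and length are deliberate package
choices — radius 2, 2048 bits — because they are the de facto QSAR standard
produced by the underlying cheminformatics toolkit; both are configurable
(`QSARConfig.n_bits`, `.radius`, minimum 64 bits). Forest defaults are 500
trees, unlimited depth, fixed seed; 5-fold cross-validation metrics are
retained on the fitted model. One model is fitted per target; a pooled model
(all targets relabelled to one) is supported for downstream potency
prediction and is the pipeline default, since candidate profiling needs a
single potency estimate per compound.

Evaluation reports MSE, R², MAE and RMSE, with RMSE computed as √MSE so the
identity holds to machine precision.

## Applicability domain

The domain filter runs in two stages. Stage 1 keeps records with
pIC50 ≥ 5.0 (configurable), removing weak binders before residual analysis.
Stage 2 computes absolute residuals |observed − predicted| on the stage-1
records and excludes those above the 95th-percentile cutoff. Residuals are
taken as absolute values: a signed 95th percentile would remove only
under-predictions, whereas outlier removal here is symmetric. The quantile
uses linear interpolation between order statistics (the common default,
`numpy.quantile(method="linear")`), verified in tests against an independent
hand-rolled interpolation oracle to 1e−12. By the quantile definition the
filter always retains at least ⌈0.95·n⌉ − 1 records; when 0.95·n is integral
this equals a 95% retained fraction exactly, otherwise the guaranteed
fraction can fall marginally below 95% (e.g. 164/173), which is a property
of interpolated quantiles, not of the implementation.

## Similarity matching

Candidates are matched to known actives by cosine similarity of their
fingerprints, dot(a,b)/(‖a‖‖b‖) ∈ [0,1] for binary vectors. A (candidate,
target) pair is a hit when the best similarity over that target's actives is
**strictly** greater than the threshold (default 0.5); the boundary case is
covered by a dedicated test. A candidate's overall status is the union of
its per-target calls. The vectorized implementation is tested for exact
agreement with an exhaustive double-loop oracle on 100×100 instances.
Matching operates directly on fingerprints; no learned pair embedding is
used, so the decision boundary is fully transparent and needs no trained
weights.

## Clustering and SAR

Cluster count selection runs k-means across k = 2…10 and reports both the
per-k SSE (elbow: largest second difference) and the silhouette score. When
the two disagree the silhouette winner is chosen — a single k must be
reported, and silhouette directly measures cluster quality while the elbow
is a curvature heuristic. A best silhouette below 0.25 flags "no cluster
structure". Clustering features are the five physicochemical descriptors
(MW, LogP, HBD, HBA, TPSA), z-standardized, concatenated with predicted
pIC50; fingerprint bits are used only for the per-cluster bit-frequency
matrix, whose column sums conserve the global bit counts.

Potency tiers are low (pIC50 ≤ 5), medium (5 < pIC50 ≤ 7) and high
(pIC50 > 7); both boundaries are inclusive on the lower tier, and the three
classes partition the line (property-tested including the boundaries).

Maximum common substructure uses element + bond-order comparison,
rings-only matching off, 10 s timeout (all configurable); the returned
SMARTS is guaranteed to match every input molecule, with maximality only
within the timeout.

Functional groups are detected with a SMARTS library shipped as an editable
data file (`ncscreen/data/functional_groups.yaml`): ether, ketone, aldehyde,
carboxyl, aromatic. Exclusions are encoded in the patterns — a carboxyl
carbon cannot match ketone or aldehyde (those require two carbon neighbours
or a C–H on the carbonyl carbon), and ester oxygens are excluded from the
ether pattern.

## BBB permeability score

Five criteria at 20% each, all bounds inclusive as stated: MW ≤ 400 Da,
−0.5 ≤ LogP ≤ 5, HBD ≤ 3, HBA ≤ 7, TPSA ≤ 90 Å². Descriptors come from the
same layer used everywhere else — Crippen atom-contribution LogP, Ertl
fragment TPSA, Lipinski donor/acceptor counts — so SAR tables and BBB flags
can never disagree. The regression suite pins the scores of five reference
flavonoids computed from their structures: coumarin 100%, dihydromyricetin
40%, quercetin 60%, kaempferol 60%, luteolin 60%.

Two other commonly cited reference values are **not** reproduced by these
criteria with standard descriptor definitions and are deliberately excluded
from the regression suite rather than forced: astragalin (sometimes quoted
at 60%) computes to 20% (MW 448 > 400, HBD 7, HBA 11, TPSA 190 Å²), and
apigenin (sometimes quoted at 100%) computes to 80% because its TPSA of
90.90 Å² marginally exceeds the 90 Å² bound. Descriptor definitions are not
tuned to force agreement.

## Synthetic data generator

The generator exists so every stage is testable without database downloads.

* **Compounds** are built by decorating a small scaffold library (benzene,
  chromone, flavone, coumarin, pentane, cyclohexanone) with 0–3 substituents
  (OH, OMe, COOH, CHO, CH₃) attached only to carbons with a free hydrogen;
  the grammar therefore cannot produce valence errors, verified by a
  10,000-draw parse-all test. Shared scaffolds give candidates and actives
  genuine common substructure, which the similarity and MCS stages require.
* **Activities** plant a linear signal: pIC50 = 6.5 + Σ wᵦ·bitᵦ + N(0, σ²)
  with σ = 0.3 by default. Signal bits are chosen among fingerprint
  positions set in 20–80% of the cohort (12 bits, weights ±0.4–0.8), giving
  a signal SD near 1 pIC50 unit — a realistic assay-noise-to-signal ratio
  under which the planted structure is recoverable but not trivial.
* **Cluster fixtures** are Gaussian blobs whose centres are rejection-
  sampled to pairwise separations of ≥ 10 within-blob SDs (4 dimensions).
* **Source fixtures** plant six food sources with counts 40/37/32/32/31/31
  and a 25-compound core present in all six, mirroring the shape of a
  top-foods analysis over a food–compound database.

What passing these tests shows: the pipeline recovers structure it is
guaranteed to contain. What it does not show: performance on real screening
libraries, whose activity landscapes are not linear in fingerprint bits,
whose assay noise is not Gaussian or homoscedastic, and whose chemistry is
far more diverse than six scaffolds.

## Problem sizes and determinism

Test and acceptance workloads are desk-scale by design: QSAR recovery uses
n = 500 compounds over 5 seeds, cluster-count recovery 240 points over 20
seeds, the matcher oracle 100×100 pairs, and the end-to-end pipeline test
120 compounds with a 60-tree forest. All randomness flows through explicit
integer seeds (numpy `default_rng`, scikit-learn `random_state`); rerunning
a pipeline with the same config and seed reproduces the manifest hash.

## Known limitations

* The stage that reads the candidate table is `featurize`, so a corrupt
  candidates file fails there, not at `predict-nc`.
* The similarity matcher scores raw fingerprints; it will not reproduce the
  behaviour of learned pair-embedding models beyond their stated 0.5
  cosine decision rule.
* Per-target metrics from database-scale ligand sets (tens of thousands of
  ligands per target) are out of reach of the synthetic fixtures and are
  not claimed.
* Salts are reduced to the largest organic fragment before featurization;
  stereochemistry is preserved when present but never required.
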