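# pcmlab

Proteochemometric (PCM) binding-affinity modeling with conformal prediction
intervals, as a tested end-to-end pipeline on synthetic ChEMBL-like data
with known ground truth.

## The problem

Predicting protein–ligand binding affinity (pIC50) from public bioactivity
data requires a long chain of steps, each with quiet failure modes: record
curation (units, confidence, comments, duplicate flags, PAINS
substructures, molecular-weight windows, replicate aggregation), ligand and
protein featurization, splits that do not leak chemistry between training
and validation, models whose per-instance uncertainty is meaningful, and
prediction intervals that actually cover the truth at their stated
confidence. `pcmlab` implements that chain for PCM regression — one model
spanning many protein targets by concatenating ligand and protein
descriptors — and, because real bioactivity corpora are large, external and
unversioned, ships a synthetic-data generator that emulates their
statistical structure (related protein families, scaffold-structured ligand
libraries, publication-biased labels with ~0.5 log-unit heteroscedastic
noise, curation contaminants) so every stage is testable against a
manifest of what a correct analysis must recover.

## The model

A pair (molecule *m*, protein *p*) is featurized as

    x = [ ECFP6(m; 4096 bits) | physchem(m; 8) | AAC|DPC|CTD(p; 20+400+147) ]

(4671 columns; the continuous blocks standard-scaled on training rows
only). Labels are pIC50 = 9 − log10(IC50/nM), standard-scaled on training
labels. Two regressors are provided:

* **RF** — random forest (scikit-learn) with per-instance spread
  σ(x) = population SD of the individual tree predictions;
* **FFN** — a 3-layer feed-forward net (2000/1000/500, ReLU → batch norm →
  dropout 0.25) in which each fingerprint bit is a 2-category entity
  embedding learned by backpropagation; spread via MC-dropout
  (test-time dropout over repeated stochastic passes).

Inductive conformal regression turns spread into intervals. With
nonconformity α = |y − ŷ| / (σ(x) + β) on a held-out calibration set of
size n, the (1−ε) interval is ŷ ± α*·(σ(x) + β) where α* is the k-th
smallest calibration score, k = ⌈(1−ε)(n+1)⌉ (unbounded if k > n). Under
exchangeability, coverage ≥ 1−ε marginally. Validity (empirical coverage)
and efficiency (interval width) are the evaluation axes, next to MSE,
Pearson r and Kendall τ-b.

Splits: generic Bemis-Murcko scaffold split (no validation compound shares
a generic scaffold with training), random split, held-out-protein split,
and the nested random training/calibration split used for conformal
calibration.

## Worked example

```python
from pcmlab import conformal
from pcmlab.curation import LabelScaler
from pcmlab.evaluation import regression_metrics
from pcmlab.models import RFConfig, rf_predict_uncertainty, train_rf
from pcmlab.splits import calibration_split, scaffold_split
from pcmlab.synthetic import SyntheticConfig
from pcmlab.workflows import make_dataset, _assemble_subsets

ds = make_dataset(SyntheticConfig(seed=0))          # generate + curate
print(f"curated pairs: {len(ds.pic50)}  proteins: {len(set(ds.protein_ids))}  "
      f"mean pIC50: {ds.pic50.mean():.2f}")

ids = list(range(len(ds.pic50)))
split = calibration_split(scaffold_split(ids, ds.smiles, 0.8, seed=0), 0.8, seed=0)
tr, ca, va = list(split.train_ids), list(split.calibration_ids), list(split.valid_ids)
scaler = LabelScaler.fit(ds.pic50[tr])
X_tr, X_ca, X_va = _assemble_subsets(ds, [tr, ca, va], n_bits=4096)
model = train_rf(X_tr, scaler.transform(ds.pic50[tr]), RFConfig(n_estimators=500, seed=0))

pred_va = rf_predict_uncertainty(model, X_va)
m = regression_metrics(scaler.transform(ds.pic50[va]), pred_va.mean)
print(f"held-out-scaffold validation: MSE={m.mse:.2f}  r={m.pearson_r:.2f}  "
      f"tau={m.kendall_tau:.2f}")

pred_ca = rf_predict_uncertainty(model, X_ca)
calib = conformal.fit_calibrator(scaler.transform(ds.pic50[ca]),
                                 pred_ca.mean, pred_ca.spread)
iv = conformal.predict_interval(pred_va.mean, pred_va.spread, calib, epsilon=0.05)
cov = conformal.validity(iv, scaler.transform(ds.pic50[va]))
print(f"95% intervals: coverage={cov:.3f}  "
      f"median width={conformal.efficiency(iv)['median']:.2f} scaled pIC50")
```

prints (seed 0):

```
curated pairs: 2016  proteins: 24  mean pIC50: 6.51
held-out-scaffold validation: MSE=0.36  r=0.59  tau=0.51
95% intervals: coverage=0.937  median width=1.86 scaled pIC50
```

The curated table has 2016 (molecule, protein) pairs whose label
distribution is publication-biased around pIC50 ≈ 6.5. On compounds whose
generic scaffold was never seen in training, the forest explains part of
the latent signal (r = 0.59 against a noise-limited ceiling set by the 0.5
log-unit label noise), and the conformal intervals cover 93.7% of held-out
scaffold truths — close to the nominal 95% even though scaffold-held-out
data are not exchangeable with the calibration set.

A command-line mirror of the stages is available:
`pcmlab simulate|curate|featurize|split|train|conformal|evaluate`.

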