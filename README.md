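# cpqsar

A counter-propagation artificial neural network (CP ANN) toolkit for
carcinogenicity QSAR modelling of non-congeneric chemicals, integrated with
the Benigni–Bossa structural-alert (SAR) rulebase and Kohonen-map analytics
for mechanistic interpretation.

Carcinogenicity screening of structurally diverse ("non-congeneric")
chemicals is hard precisely because no single mechanism covers the whole
chemical space. This package combines the two standard strategies:

- **QSAR**: a statistical classifier — a CP ANN over twelve topological and
  fragment-count molecular descriptors — predicts the rodent carcinogenicity
  class (1 = non-carcinogen NP, 2 = carcinogen P);
- **SAR**: a knowledge-based rulebase of 33 structural alerts (SAs) —
  substructures mechanistically or statistically linked to carcinogenesis,
  each tagged genotoxic (GA) or non-genotoxic (nGA) — annotates the same
  chemicals;
- **interpretation**: because the CP ANN is a self-organizing map, its
  weight levels, output surface and top map are 2-D fields that can be read
  directly, so the alert families can be located on the trained map and
  compared with the descriptors' influential zones.

It is intended for computational toxicologists and cheminformaticians who
want a transparent, fully inspectable carcinogenicity model rather than a
black box.

## The model

A CP ANN is a Kohonen self-organizing map of `nx x ny` neurons extended with
a supervised output layer of identical layout. Each neuron `c` carries a
weight vector `w_c` in descriptor space (the stack of `p` grid slices are
the *weight levels*) and an output vector `o_c`. For each training object
`(x_i, y_i)` the *winning* neuron minimizes `||x_i − w_c||`; all neurons
within the current neighbourhood radius move toward the object in **both**
layers,

    w_c ← w_c + η_t · h(d_c) · (x_i − w_c)
    o_c ← o_c + η_t · h(d_c) · (y_i − o_c)

with a triangular neighbourhood `h(d) = max(0, 1 − d/(r_t + 1))` on the
Chebyshev grid distance `d_c`, learning rate `η_t` decaying linearly from
`η_max` to `η_min` and radius `r_t` shrinking linearly from `max(nx,ny)/2`
to 0 over the run. Prediction projects a new object onto its winner and
decodes the output weights stored there (threshold 1.5 for the numeric 1/2
class coding; argmax for the one-hot alert-group coding).

The twelve descriptors (columns `PW5, D/Dr06, MATS2p, EEig10x, ESpm11x,
ESpm09d, GGI2, JGI6, nRNNOx, nPO4, N-067, N-078`) are computed from the
H-depleted molecular graph: the Randić path/walk-5 shape index, the
distance/detour ring index of order 6, the polarizability-weighted Moran
autocorrelation at lag 2, an eigenvalue and two spectral moments of the
(edge-degree- and dipole-weighted) edge adjacency matrix, two Galvez
topological charge indices, and four fragment counts (aliphatic N-nitroso,
phosphate/thiophosphate, Al2-NH, Ar-N=X / X-N=X). A Fisher-ratio +
cross-correlation screening module reproduces the statistical pre-selection
step, and stratified hold-out, 5-fold ("leave 20 % out") cross-validation
and external evaluation cover validation.

## Worked example

```python
from cpqsar import (load_rulebase, match_alerts, group_label,
                    compute_descriptor_block, MoleculeRecord)
from cpqsar.cpann import CPANNClassifier
from cpqsar.synthetic import SyntheticSpec, generate_gaussian_classes
from cpqsar.validation import stratified_split, evaluate

rb = load_rulebase()
rec = MoleculeRecord(id="ndma", name="N-nitrosodimethylamine", smiles="CN(C)N=O")
ann = match_alerts(rec, rb)
print(f"alerts: {sorted(ann.alerts)}  mechanism: {ann.mechanism_summary}  "
      f"group: {group_label(ann)}")

print(compute_descriptor_block([rec]).to_frame().round(3).to_string())

X, y = generate_gaussian_classes(SyntheticSpec(n_per_class=100, p=12,
                                               separation=4.0, seed=0))
train_idx, test_idx = stratified_split(X.values, y, test_fraction=0.2, seed=0)
clf = CPANNClassifier(nx=10, ny=10, epochs=100, random_state=0)
clf.fit(X.values[train_idx], y[train_idx])
report = evaluate(clf, X.values[test_idx], y[test_idx])
print(f"held-out accuracy {report.accuracy:.3f}  "
      f"sensitivity {report.sensitivity:.3f}  specificity {report.specificity:.3f}")
```

prints

```
alerts: ['SA_21']  mechanism: GA  group: 5
      PW5  D/Dr06  MATS2p  EEig10x  ESpm11x  ESpm09d   GGI2  JGI6  nRNNOx  nPO4  N-067  N-078
ndma  0.0     0.0   0.206      0.0    0.677    9.019  0.444   0.0     1.0   0.0    0.0    1.0
held-out accuracy 0.950  sensitivity 0.950  specificity 0.950
```

N-nitrosodimethylamine carries the alkyl-N-nitroso alert SA_21 (a genotoxic
alert, map group 5), and its descriptor row shows the two nitroso-sensitive
fragment counts (`nRNNOx`, `N-078`) firing — the same association the map
analytics expose on a trained model. The classifier block shows a CP ANN
recovering two synthetic descriptor-space classes separated by 4 within-class
standard deviations.

The `cpqsar` command line mirrors the library
(`descriptors`, `alerts`, `select`, `train`, `predict`, `cv`, `maps`,
`simulate`, `run`); `cpqsar run config.yaml` executes the whole pipeline
into a run directory with a manifest.

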