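# gipredict

Interpretable prediction of how single, double and triple gene
knockouts affect organismal viability, from protein–protein-interaction
(PPI) network topology and gene annotations.

## The problem

Deleting a gene can be lethal, reduce growth, or leave fitness normal
(classes L / R / N); deleting two or three genes together can deviate
from the single-knockout expectation — a genetic interaction (GI),
classed as negative (including synthetic lethality), positive,
suppression, or neutral. These outcomes matter for identifying
essential genes and disease-specific vulnerabilities, but the datasets
are severely imbalanced (negative GIs are roughly 0.8% of double
knockouts), and black-box classifiers evaluated with AUC-ROC on such
data overstate their skill. `gipredict` implements the alternative: a
family of open-box multinomial regression models evaluated with
imbalance-aware metrics, with neural baselines to show the linear
models give nothing away.

## The models

Each model specifies, per non-reference output class *x*, the log odds
against a reference class (normal growth, or neutral GI):

* single gene (S-MN):
  `log(p_x/p_N) = β0x + β1x·LID + β2x·Pident + Σ_i β(i+2)x·sGO_i`
* gene pair (D-MN):
  `log(p_x/p_n) = φ0x + φ1x·(LID_A+LID_B) + φ2x·LL + … + φ7x·NN
  + φ8x·SPL + Σ_i φ(i+8)x·(sGO_iA+sGO_iB)`
* gene triplet (T-MN): same construction with ΣLID, the ten unordered
  fitness combinations, the shortest circuit length (SCL) and per-term
  sharing counts.

Features: **LID** is the local interaction density — the edge density
among a protein's direct PPI neighbours after its removal, a proxy for
the internal connectedness of its complex. **Pident** is the percent
identity of the closest within-genome homolog (a backup-gene proxy).
**sGO** terms are ~45 broad slim Gene Ontology memberships. **SPL/SCL**
are shortest-path distances between the pair (or around the triple) in
the PPI network. Pair and triplet encodings are symmetric functions of
the genes, so predictions are exactly order-invariant.

Coefficients are learned by SGD on class-weighted categorical
cross-entropy and exponentiate to odds factors: `exp(β)` is the
multiplicative change in class-vs-reference odds per unit of the
feature. Evaluation uses balanced accuracy `BA = (1/K) Σ_c f_cc/N_c`
(0.5/0.33/0.25 for a no-skill 2/3/4-class model), confusion matrices
and per-class one-vs-rest AUC, with repeated stratified
cross-validation. Exhaustive feature-set selection (all 2^m − 1
category subsets; 127 for seven categories) finds the smallest feature
set within tolerance of the best BA. Feed-forward and weight-shared
Siamese networks provide the black-box reference points, and a
synthetic-data generator produces networks, annotations, complexes and
labels from known ground-truth coefficients so the whole pipeline is
testable without downloads.

## Worked example

Generate a synthetic study, fit the single-gene model, and evaluate it
on a held-out split:

```python
from gipredict import mn, simulate as sim, evaluate as ev

truth = sim.default_ground_truth()
net = sim.generate_network(truth.n_genes, truth.attachment_m, seed=0)
table = sim.generate_annotations(sim.gene_ids(truth.n_genes), seed=1)
singles = sim.generate_single_labels(table, net, truth.s_mn, seed=2)

dev, test = ev.split_dev_test(singles.y, test_fraction=0.2, seed=3)
model = mn.fit_mn(singles.X[dev], singles.y[dev],
                  classes=("L", "R", "N"), reference_class="N",
                  feature_names=singles.layout.names,
                  config=mn.TrainingConfig(seed=4))
report = ev.evaluate_classifier(singles.y[test],
                                model.predict_proba(singles.X[test]),
                                ("L", "R", "N"))
print(f"held-out balanced accuracy: {report.ba:.3f}")
print(model.odds_factors().loc[["lid", "pident", "sgo:sGO00"]].round(3))
```

prints

```
held-out balanced accuracy: 0.511
               L      R
lid        8.591  1.352
pident     0.989  0.998
sgo:sGO00  3.256  1.465
```

Balanced accuracy 0.511 against a three-class chance rate of 0.333
(the 1000-gene study is deliberately noisy). The odds-factor table
reads directly: a unit increase in LID multiplies the odds of a lethal
outcome by 8.6; each percentage point of homolog identity lowers them
by ~1%; carrying the first slim-GO term raises them 3.3-fold — the
kind of sentence a black-box model cannot produce.

The same workflow is scriptable from a shell:

```bash
gipredict simulate --out study/ --seed 0
gipredict lid-table study/ppi_edges.tsv --out study/lid.tsv
gipredict fit-single study/ppi_edges.tsv study/annotations.tsv vocab.txt --out smn.json
gipredict predict-single smn.json study/ppi_edges.tsv study/annotations.tsv vocab.txt --out pred.tsv
```

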