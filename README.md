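# pkaqsar

An open QSAR pipeline for predicting the aqueous acid dissociation
constant (pKa) of small organic molecules, with the full machinery
around the models: data curation, acid/base routing, applicability
domain, and predictor benchmarking.

## Who this is for

Cheminformaticians and drug-discovery / environmental-fate modelers who
need macroscopic pKa estimates (strongest acidic and strongest basic
site) from 2D structure alone, and who want the complete, inspectable
chain from raw experimental records to an annotated prediction rather
than a black-box number.

## What it does

1. **Curation** — raw records (SMILES, pKa, acidic/basic label) are
   standardized to QSAR-ready parent structures: salts, solvents and
   counterions stripped; mixtures and inorganics rejected; nitro
   mesomers and keto–enol tautomers canonicalized; zwitterions left as
   drawn. Replicate measurements are grouped per structure and per
   class, and three modeling-set options handle replicate variability:
   Option 1 keeps only single-measurement chemicals; Option 2 averages
   replicates with sample SD < 2 pKa units; Option 3 keeps everything,
   averaging when SD ≤ 1 and otherwise taking the strongest value
   (minimum acidic, maximum basic). Train/test splits (75/25) are
   stratified on 1-pKa-unit bins crossed with replicate/amphoteric
   flags so both sets share the same pKa distribution.
2. **Featurization** — 1D/2D continuous descriptors, binary
   fingerprints (MACCS, circular, path-based) and fragment counts, with
   a D1/D2/D3 reduction ladder (constants → |r| ≥ 0.95 correlated pairs
   → low variance) and [−1, 1] min–max scaling fit on training rows.
3. **Routing** — a genetic algorithm selects a compact continuous
   descriptor subset that separates acidic / basic / amphoteric
   structures (fitness: fivefold-CV multiclass balanced accuracy,
   BA = mean of per-class recalls); a kNN majority vote routes each
   query, gated by an ionizability checker (≥ 1 H-bond donor or
   acceptor site).
4. **Regression** — three branches trained per ionization class:
   epsilon-SVR (RBF), gradient-boosted trees, and a fully connected
   neural network (3 × 256 ReLU), all tuned by fivefold-CV RMSE and
   reported as R² (fit), Q² (out-of-fold) and R²/RMSE (test).
5. **Applicability domain** — global Boolean index from the leverage
   h = x(XᵀX)⁻¹xᵀ against h* = 3p/n, plus a local continuous index in
   [0, 1]: the mean Jaccard–Tanimoto similarity of the k nearest
   training fingerprints, with a neighbor-residual accuracy estimate.
6. **Benchmarking** — pairwise ±2-pKa-unit concordance between
   predictor tables, benchmark construction by averaging concordant
   predictions, pKa-range filtering, and 5000-resample percentile
   bootstrap confidence intervals for R², r² and RMSE.

A deterministic synthetic-record generator (template + decoration
group-contribution oracle, with replicates, salts, mixtures and
inorganics injected) makes every stage testable without any data
download.

## Worked example

```python
from pkaqsar import FixtureSpec, TrainConfig, generate_fixture, train_pipeline

fx = generate_fixture(FixtureSpec(n_structures=150, noise_sd=0.4, seed=2))
predictor, report = train_pipeline(fx.records, TrainConfig(option=3, regressor="svm", seed=2))
print(predictor.predict_smiles(["CCCC", "OC(=O)c1ccc(Cl)cc1"]))
```

prints (abridged):

```
acidic: test RMSE 0.63 pKa units, test R2 0.95, Q2 0.91
basic:  test RMSE 1.01 pKa units, test R2 0.87, Q2 0.92
            smiles  ionizable pka_class  acidic_pka  basic_pka
              CCCC      False      None         NaN        NaN
OC(=O)c1ccc(Cl)cc1       True    acidic    3.628759        NaN
```

Butane has no donor/acceptor site, so the ionizability checker emits no
pKa at all. 4-chlorobenzoic acid is routed to the acidic regressor; the
predicted 3.63 sits below the unsubstituted benzoic-acid training value,
as the chloro substituent's electron withdrawal demands. Every predicted
row also carries leverage, local-index and accuracy-estimate columns.

The `examples/` directory has one short script per capability
(curation/options, GA + routing, train/predict, applicability domain,
concordance benchmarking); each prints the numbers it computes and what
they mean. A thin CLI mirrors the same flow
(`pkaqsar curate|featurize|select-descriptors|train|predict|benchmark|fixture`).

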