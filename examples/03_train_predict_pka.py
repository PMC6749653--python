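"""Train the full pipeline and predict pKa for new structures.

The deployment flow: ionizability check -> acid/base/amphoteric routing
-> per-class regressor -> applicability-domain annotation.
"""

from pkaqsar import FixtureSpec, TrainConfig, generate_fixture, train_pipeline

fx = generate_fixture(FixtureSpec(n_structures=150, noise_sd=0.4, seed=2))
predictor, report = train_pipeline(fx.records, TrainConfig(option=3, regressor="svm", seed=2))

for cls, m in report["metrics"].items():
    print(f"{cls}: test RMSE {m.rmse_test:.2f} pKa units, test R2 {m.r2_test:.2f}, "
          f"Q2 {m.q2_cv:.2f}")

queries = [
    "CCCC",              # butane: not ionizable, no pKa is emitted
    "OC(=O)c1ccc(Cl)cc1",  # 4-chlorobenzoic acid
    "NCC(=O)O.[Na+].[Cl-]",  # glycine salt: counterions stripped first
]
result = predictor.predict_smiles(queries)
cols = ["smiles", "ionizable", "pka_class", "acidic_pka", "basic_pka"]
print(result[cols].to_string(index=False))
# amphoteric structures get both an acidic and a basic pKa; each carries
# its own applicability-domain fields (see example 04)
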