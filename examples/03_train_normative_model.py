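"""Train the normative age model on a small healthy cohort.

Fits the 10-fold gradient-boosted regression of chronological age on the
JID features and reports out-of-fold performance: mean error (ME, signed;
positive = predicted older), mean absolute error (MAE) and R^2 (squared
correlation of predicted vs real age).  A small cohort and a light
boosting configuration keep this example fast; the full configuration
(depth 9, 567 trees) is the library default.
"""

import tapage as tp

cfg = tp.GeneratorConfig(n_subjects=80, days_range=(14, 60), seed=1)
streams, records = tp.generate_cohort(cfg)
streams, records = tp.apply_inclusion_filter(records, streams, min_days=7)
table = tp.build_feature_table(streams, records, window_days=60)

folds = tp.make_folds(table, k=10, seed=1)
light = tp.ModelHyperparams(max_depth=4, n_trees=120, learning_rate=0.1, min_child_weight=2.0)
bundle = tp.train_normative(table, folds, light, seed=1)

oof = tp.predict_out_of_fold(bundle, table)
m = tp.performance_metrics(oof)
print(f"subjects: {len(table)}; folds: {bundle.n_folds}")
print(f"out-of-fold ME  : {m['ME']:+.2f} years (bias of the age estimates)")
print(f"out-of-fold MAE : {m['MAE']:.2f} years (typical absolute miss)")
print(f"out-of-fold R2  : {m['R2']:.3f} (squared corr., predicted vs real age)")
baseline, _ = tp.null_input_prediction(bundle)
print(f"null-input baseline prediction: {baseline:.1f} years (all-zero features)")
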