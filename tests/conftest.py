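"""Shared fixtures: a small synthetic cohort and a quick trained bundle.

Unit tests use reduced cohort sizes and lightweight boosting settings so
the suite stays fast; the structural properties under test do not depend on
the full-size configuration.
"""

import numpy as np
import pytest

import tapage as tp

SMALL_SEED = 5


@pytest.fixture(scope="session")
def small_cohort():
    cfg = tp.GeneratorConfig(
        n_subjects=60,
        days_range=(7, 40),
        mean_daily_taps=80.0,
        seed=SMALL_SEED,
    )
    streams, records = tp.generate_cohort(cfg)
    return cfg, streams, records


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, streams, records = small_cohort
    streams, records = tp.apply_inclusion_filter(records, streams, min_days=7)
    return tp.build_feature_table(streams, records, window_days=30)


SMALL_HP = tp.ModelHyperparams(max_depth=4, n_trees=80, learning_rate=0.1, min_child_weight=2.0)


@pytest.fixture(scope="session")
def small_bundle(small_features):
    folds = tp.make_folds(small_features, k=10, seed=SMALL_SEED)
    return tp.train_normative(small_features, folds, SMALL_HP, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_oof(small_bundle, small_features):
    return tp.predict_out_of_fold(small_bundle, small_features)
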