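from __future__ import annotations

import numpy as np
import pytest

from microdyn import pipeline
from microdyn.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3+3 subjects, 30 s, moderate noise — fast end-to-end fixture."""
    cfg = GeneratorConfig(n_per_group=3, duration=30.0, noise_sd=0.5, seed=7)
    recordings, groups, gt = generate_cohort(cfg)
    return cfg, recordings, groups, gt


@pytest.fixture(scope="session")
def small_segmented(small_cohort):
    cfg, recordings, groups, gt = small_cohort
    templates, epochsets, labels = pipeline.segment_cohort(recordings, K=cfg.K,
                                                           seed=42)
    return cfg, templates, epochsets, labels, groups, gt


@pytest.fixture(scope="session")
def study_cohort_table():
    """28+28 subjects under the default study conditions, featurized.

    Duration is reduced to 60 s (vs the 150 s default) to keep the suite
    fast; every planted effect is unchanged.  Returns the feature table
    plus the planted -> learned state correspondence (template matching),
    since learned templates are ordered by cluster size, not by planted
    index.
    """
    import pandas as pd
    from scipy.optimize import linear_sum_assignment

    cfg = GeneratorConfig(duration=60.0)
    recordings, groups, gt = generate_cohort(cfg)
    templates, epochsets, labels = pipeline.segment_cohort(recordings,
                                                           K=cfg.K, seed=42)
    rows = [pipeline.subject_features(es, lab, K=cfg.K)
            for es, lab in zip(epochsets, labels)]
    table = pd.DataFrame(rows, index=[r.subject for r in recordings])
    table["group"] = groups
    cos = np.abs(templates.maps @ gt.templates.maps.T)
    learned, planted = linear_sum_assignment(-cos)
    state_map = {int(p): int(l) for l, p in zip(learned, planted)}
    return cfg, table, gt, state_map


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
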