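"""Shared fixtures.

The expensive artifacts — the labeled training corpus, the trained peak
classifier and the estimated traces across artifact gains — are built once
per session and reused by the unit and acceptance tests.  Session lengths
are kept short (60-120 s, i.e. 27-57 analysis windows) so the whole suite
runs in minutes; the windowing, grids and all method parameters are the
standard operating point.
"""

import numpy as np
import pytest

from wristhr import (HeartRateModel, PipelineConfig, SimConfig,
                     simulate_session, simulate_training_corpus)
from wristhr.tracking import train_classifier

CORPUS_SEED = 7
SESSION_SEED = 42
GAINS = (0.0, 0.5, 1.0, 2.0)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def corpus(cfg):
    """Labeled (C, S) features pooled from 5 short mixed-regime sessions."""
    feats, labs = simulate_training_corpus(
        n_sessions=5, seed=CORPUS_SEED, duration_s=60, pipeline_cfg=cfg
    )
    return feats, labs


@pytest.fixture(scope="session")
def classifier(corpus):
    feats, labs = corpus
    return train_classifier(feats, labs)


@pytest.fixture(scope="session")
def gain_results(cfg, classifier):
    """Fitted results and truth for one seeded session at several artifact gains."""
    out = {}
    for alpha in GAINS:
        sim = SimConfig(seed=SESSION_SEED, duration_s=120,
                        artifact_gain=(alpha, alpha))
        record, truth = simulate_session(sim, cfg)
        res = HeartRateModel(record, classifier, cfg).fit()
        out[alpha] = (res, truth)
    return out
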