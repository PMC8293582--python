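import dataclasses

import numpy as np
import pytest

from bfsmr import (
    DEFAULT_ALIASES,
    WeightScheme,
    canonicalize,
    default_cohort_config,
    default_rank_weights,
    generate_cohort,
    inject_missingness,
    load_reference_lists,
    schema_from_cohort_config,
    tally_votes,
    write_cohort,
)
from bfsmr.ingest import ingest_file

#: model weights of the five reference selectors (performance tiers 1/0.5/0.2)
REFERENCE_W2 = {
    "lasso": 1,
    "ridge": 1,
    "filter_mi": 0.5,
    "svm_rfe": 0.5,
    "random_forest": 0.2,
}


@pytest.fixture(scope="session")
def reference_lists():
    return load_reference_lists()


@pytest.fixture(scope="session")
def reference_scheme():
    return WeightScheme(w1=default_rank_weights(10), w2=REFERENCE_W2)


@pytest.fixture(scope="session")
def reference_tallies(reference_lists, reference_scheme):
    canonical, _ = canonicalize(reference_lists, DEFAULT_ALIASES)
    return {s: tally_votes(canonical, s, reference_scheme) for s in ("voting1", "voting2", "voting3")}


@pytest.fixture(scope="session")
def encoded_cohort(tmp_path_factory):
    """A 12,000-record default-condition cohort, encoded as a single chunk."""
    cfg = default_cohort_config(12_000, master_seed=42)
    cohort = inject_missingness(generate_cohort(cfg))
    path = tmp_path_factory.mktemp("cohort") / "cohort.csv"
    write_cohort(cohort, path)
    schema = schema_from_cohort_config(cfg)
    (chunk,) = ingest_file(path, schema, chunk_size=len(cohort.records))
    return chunk


def make_planted_classification(n, seed, effects=(3.0, -2.8), n_features=12, noise_sd=2.0):
    """Direct planted-effect binary problem: label = linear score above its 90th pct."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    eta = sum(e * X[:, i] for i, e in enumerate(effects))
    score = eta + rng.normal(0, noise_sd, size=n)
    y = (score > np.quantile(score, 0.9)).astype(int)
    names = [f"f{i}" for i in range(n_features)]
    return X, y, names


def small_config(n_records=2_000, seed=0, **overrides):
    cfg = default_cohort_config(n_records, master_seed=seed)
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
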