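"""Shared fixtures.

The expensive end-to-end objects are session-scoped: ``chain0`` runs the
selection chain once on the default synthetic study conditions, and
``pipeline_runs`` executes the full orchestrated pipeline twice with one
configuration (the pair is used both for recovery checks and for the
byte-level determinism check).
"""

from __future__ import annotations

import numpy as np
import pytest

from cellmark import (
    BorutaConfig,
    ClassifierSpec,
    ExpressionMatrix,
    IFSConfig,
    LabelVector,
    MCFSConfig,
    PipelineConfig,
    SynthConfig,
    max_relevance_filter,
    run_all,
    run_boruta,
    run_ifs,
    run_mcfs,
    simulate_profiles,
)


@pytest.fixture
def tiny_data():
    """12 cells × 4 genes, 2 classes; gene G0 separates the classes."""
    rng = np.random.default_rng(42)
    n = 12
    y = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
    X = rng.poisson(2.0, size=(n, 4)).astype(float)
    X[y == "b", 0] += 10.0
    m = ExpressionMatrix(X, [f"G{j}" for j in range(4)], [f"c{i}" for i in range(n)])
    return m, LabelVector(y)


@pytest.fixture(scope="session")
def synth0():
    """Default synthetic study conditions at seed 0, with planted truth."""
    return simulate_profiles(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def chain0(synth0):
    """Full selection chain on ``synth0``: MI filter → shadow-feature
    confirmation → Monte Carlo ranking → IFS with a random forest."""
    matrix, labels, truth = synth0
    relevance = max_relevance_filter(matrix, labels)
    boruta = run_boruta(
        matrix.subset_genes(relevance.retained), labels, BorutaConfig(seed=0)
    )
    passed = [g for g in relevance.retained
              if g in boruta.confirmed or g in boruta.tentative]
    ranked = run_mcfs(matrix.subset_genes(passed), labels, MCFSConfig(seed=0))
    curve_rf = run_ifs(
        matrix, labels, ranked,
        IFSConfig(classifier=ClassifierSpec(kind="random_forest", seed=0), seed=0),
    )
    return {
        "matrix": matrix, "labels": labels, "truth": truth,
        "relevance": relevance, "boruta": boruta, "passed": passed,
        "ranked": ranked, "curve_rf": curve_rf,
    }


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two independent full pipeline executions with one configuration."""
    cfg = PipelineConfig(seed=0)
    dirs = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp(name)
        run_all(cfg, out)
        dirs.append(out)
    return {"config": cfg, "dirs": dirs}


TINY_PIPELINE_KW = dict(
    seed=11,
    synth=SynthConfig(n_classes=3, class_sizes=[30, 20, 12], n_genes=30,
                      markers_per_class=3, seed=11),
    boruta=BorutaConfig(max_iter=15, n_trees=25),
    mcfs=MCFSConfig(m=3, s=60, t=2),
    ifs_step=2,
    ifs_max_features=10,
    ifs_folds=5,
    rf_trees=25,
)


@pytest.fixture
def tiny_pipeline_config():
    """A miniature pipeline configuration that runs in seconds."""
    return PipelineConfig(**TINY_PIPELINE_KW)
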