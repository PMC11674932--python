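import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from hemiconn.connectome import Connectome, DistanceGraph


def make_connectome(weights, lengths, hemisphere, cortical=None, labels=None):
    n = len(hemisphere)
    return Connectome(
        labels=labels or [f"r{i}" for i in range(n)],
        hemisphere=np.array(hemisphere, dtype=object),
        cortical=np.ones(n, dtype=bool) if cortical is None else np.array(cortical),
        weights=np.asarray(weights, dtype=float),
        lengths=np.asarray(lengths, dtype=float),
    )


@pytest.fixture
def four_node():
    """L1,L2,R1,R2 with L1L2=30, R1R2=30, L1R1=20, L2R2=20, unit lengths."""
    w = np.array([
        [0, 30, 20, 0],
        [30, 0, 0, 20],
        [20, 0, 0, 30],
        [0, 20, 30, 0],
    ], dtype=float)
    lengths = (w > 0).astype(float)
    return make_connectome(w, lengths, ["L", "L", "R", "R"])


@pytest.fixture
def path3():
    """Path graph 1-2-3 with unit edge lengths."""
    e = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return DistanceGraph(labels=["a", "b", "c"],
                         hemisphere=np.array(["L", "L", "L"], dtype=object),
                         edge_length=e)


def random_distance_graph(rng, n=12, density=0.4, connected=True):
    """Random weighted graph; spanning-tree seeded when connected."""
    edge = np.zeros((n, n))
    if connected:
        perm = rng.permutation(n)
        for k in range(1, n):
            i, j = perm[k], perm[rng.integers(0, k)]
            edge[i, j] = edge[j, i] = rng.uniform(0.2, 3.0)
    for i in range(n):
        for j in range(i + 1, n):
            if edge[i, j] == 0 and rng.random() < density:
                edge[i, j] = edge[j, i] = rng.uniform(0.2, 3.0)
    hemi = np.array(["L"] * n, dtype=object)
    return DistanceGraph(labels=[f"n{i}" for i in range(n)],
                         hemisphere=hemi, edge_length=edge)


def floyd_warshall_oracle(edge_length: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths, independent of scipy."""
    n = edge_length.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and edge_length[i, j] > 0:
                d[i, j] = edge_length[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


@pytest.fixture(scope="session")
def planted_cohort():
    """A 500-subject cohort with conservation coupling -0.4, measured and
    harmonized once for the statistics/pipeline tests."""
    from hemiconn.pipeline import compute_metrics_table, harmonize_tables
    from hemiconn.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_subjects=500, seed=0, conservation_coupling=-0.4)
    cohort = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = compute_metrics_table(cohort.connectomes, cohort.records)
        h_metrics, h_records, model = harmonize_tables(metrics, cohort.records)
    return SimpleNamespace(config=cfg, cohort=cohort, records=cohort.records,
                           metrics=metrics, harmonized_metrics=h_metrics,
                           harmonized_records=h_records, combat_model=model)
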