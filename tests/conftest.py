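import numpy as np
import pytest

from aisclf import CohortSpec, generate_blobs, generate_cohort, normalize_minmax


@pytest.fixture(scope="session")
def default_cohort():
    """The registry-style cohort at its documented defaults (599 rows,
    38 recurrent, planted signal on features 2 and 10)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def separable_blobs():
    """Two well-separated Gaussian blobs, normalized to the unit cube."""
    table = generate_blobs(k=2, n_per_cluster=200, separation=8, dims=5, seed=3)
    normalized, params = normalize_minmax(table)
    return table, normalized, params


def best_cluster_accuracy(assignments, labels, k):
    """Accuracy of a clustering under the best cluster-to-label bijection
    (brute force over permutations; fine for small k)."""
    from itertools import permutations

    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    return max(
        np.mean(np.array([p[c] for c in assignments]) == labels)
        for p in permutations(range(k))
    )
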