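"""Ground-truth clustering comparison metrics.

Adjusted Rand index (chance-corrected pair-counting agreement, 0 for
random assignment, 1 for identical partitions), V-measure (harmonic mean
of entropy-based homogeneity and completeness, in [0, 1]) and the exact
O(n^2) silhouette.  Labels are opaque identifiers: both metrics are
invariant to relabeling, and every bin carries equal weight.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, silhouette_samples, v_measure_score


def _check_pair(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if len(truth) < 2:
        raise ValueError("need at least two points")
    return truth, predicted


def adjusted_rand_index(truth, predicted) -> float:
    """Pair-counting ARI = (Index - E[Index]) / (Max - E[Index]).

    Symmetric in its arguments and invariant under label permutation.
    """
    truth, predicted = _check_pair(truth, predicted)
    return float(adjusted_rand_score(truth, predicted))


def v_measure(truth, predicted) -> float:
    """Harmonic mean of homogeneity and completeness (beta = 1).

    Zero-entropy conventions: a single-cluster truth has completeness-side
    entropy 0 and scores homogeneity 1 (and symmetrically); two trivial
    single-cluster labelings score 1.
    """
    truth, predicted = _check_pair(truth, predicted)
    return float(v_measure_score(truth, predicted))


def silhouette_exact(
    features: np.ndarray, labels
) -> tuple[float, dict[int, float]]:
    """Full-pairwise silhouette: overall mean and per-cluster means.

    Serves as the oracle for the downsampled approximation in the
    analytics module; requires at least two clusters.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    values = silhouette_samples(np.asarray(features, dtype=float), labels)
    per_cluster = {int(c): float(values[labels == c].mean()) for c in ids}
    return float(values.mean()), per_cluster
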