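"""Global, local and hybrid segmentation of bins in joint RDR/BAF space.

Each bin is embedded as a 2m-dimensional feature vector — its m read-depth
ratios followed by its m B-allele frequencies.  Global segmentation fits a
Gaussian mixture with k components to these vectors and labels each bin by
its maximum-responsibility component, pooling signal genome-wide.  Local
segmentation runs a hidden Markov model along each chromosome: one state
per mixture component, component densities as emissions, a sticky
transition matrix (self-transition tau, uniform elsewhere) encoding that
copy-number aberrations tend to span large contiguous segments.  The hybrid
method chains the two: fit the mixture globally, then Viterbi-decode each
chromosome, which keeps the genome-wide component definitions while letting
genomic adjacency smooth away isolated misassignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from sklearn.mixture import GaussianMixture

from .core import BinTable, SegmentRecord, segments_from_clustering


def build_feature_matrix(table: BinTable) -> np.ndarray:
    """Stack per-bin features [RDR_1..RDR_m, BAF_1..BAF_m] into an (n, 2m) matrix."""
    return np.hstack([table.rdr, table.baf])


def fit_global_gmm(
    features: np.ndarray,
    k: int,
    seed: int,
    covariance_type: str = "diag",
    n_init: int = 10,
) -> tuple[GaussianMixture, np.ndarray]:
    """EM-fit a k-component Gaussian mixture and label bins by responsibility.

    Diagonal covariances are the default because RDR and BAF noise scales
    differ and full covariance overfits at small k; pass
    ``covariance_type="full"`` to override.  Initialization is k-means++
    seeded by `seed` with `n_init` restarts, keeping the best likelihood, so
    identical calls give identical labels.
    """
    n = features.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of bins n={n}")
    model = GaussianMixture(
        n_components=k,
        covariance_type=covariance_type,
        n_init=n_init,
        init_params="k-means++",
        random_state=seed,
        max_iter=200,
        reg_covar=1e-6,
    )
    model.fit(features)
    labels = model.predict(features)
    return model, labels


def select_k(features: np.ndarray, k_min: int, k_max: int, seed: int) -> int:
    """Pick k in [k_min, k_max] minimizing the Bayesian information criterion."""
    if not 1 <= k_min <= k_max <= features.shape[0]:
        raise ValueError("require 1 <= k_min <= k_max <= n")
    best_k, best_bic = k_min, np.inf
    for k in range(k_min, k_max + 1):
        model, _ = fit_global_gmm(features, k, seed)
        bic = model.bic(features)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def _hmm_from_mixture(model: GaussianMixture, tau: float) -> GaussianHMM:
    k = model.n_components
    hmm = GaussianHMM(
        n_components=k,
        covariance_type=model.covariance_type,
        init_params="",
        params="",
    )
    hmm.startprob_ = np.full(k, 1.0 / k)
    trans = np.full((k, k), (1.0 - tau) / (k - 1))
    np.fill_diagonal(trans, tau)
    hmm.transmat_ = trans
    hmm.means_ = model.means_
    hmm.covars_ = model.covariances_
    return hmm


def local_decode_hmm(table: BinTable, model: GaussianMixture, tau: float) -> np.ndarray:
    """Viterbi-decode bins chromosome by chromosome against the fitted mixture.

    States are the mixture components; emissions their Gaussian densities;
    transitions are tau on the diagonal and (1-tau)/(k-1) off it.  Decoding
    restarts at every chromosome boundary, so bins on different chromosomes
    never constrain each other.  At tau = 1/k the chain is memoryless and
    the decode reduces to per-bin maximum-likelihood component assignment.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    k = model.n_components
    if k == 1:
        return np.zeros(table.n, dtype=np.int64)
    features = build_feature_matrix(table)
    hmm = _hmm_from_mixture(model, tau)
    # contiguous chromosome block lengths in table order
    lengths = []
    i = 0
    while i < table.n:
        j = i
        while j + 1 < table.n and table.chrom[j + 1] == table.chrom[i]:
            j += 1
        lengths.append(j - i + 1)
        i = j + 1
    _, labels = hmm.decode(features, lengths=lengths, algorithm="viterbi")
    return labels.astype(np.int64)


@dataclass
class HybridResult:
    """Outcome of hybrid segmentation: labels, run-collapsed segments, the mixture."""

    labels: np.ndarray
    segments: list[SegmentRecord]
    model: GaussianMixture


def hybrid_segment(
    table: BinTable,
    k: int,
    tau: float = 0.99,
    seed: int = 0,
    covariance_type: str = "diag",
) -> HybridResult:
    """Global GMM fit followed by per-chromosome Viterbi decoding."""
    features = build_feature_matrix(table)
    model, _ = fit_global_gmm(features, k, seed, covariance_type=covariance_type)
    labels = local_decode_hmm(table, model, tau)
    labeled = table.copy()
    labeled.cluster = labels.copy()
    return HybridResult(labels=labels, segments=segments_from_clustering(labeled), model=model)
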