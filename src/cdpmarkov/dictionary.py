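"""Shape dictionaries: PCA denoising, cluster-count selection, k-means
prototypes, and nearest-prototype labelling.

Windows are denoised by projecting onto the principal components that
explain a target fraction of variance (98% by default) and reconstructing;
clustering and labelling both operate on this reconstruction.  The number
of clusters is chosen by consensus of two internal validity indices
(silhouette and Calinski-Harabasz); prototype labels are letters assigned
in order of decreasing cluster size.
"""

from __future__ import annotations

import logging
import string
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .errors import InvalidArgumentError

__all__ = ["PcaBasis", "ShapeDictionary", "pca_reduce", "choose_k",
           "fit_dictionary", "label_event"]

log = logging.getLogger(__name__)

DEGENERATE_SILHOUETTE = 0.1  # below this, the data shows no cluster structure


@dataclass(frozen=True)
class PcaBasis:
    components: np.ndarray  # (n_selected, d), orthonormal rows
    mean: np.ndarray
    explained_ratios: np.ndarray  # full, non-increasing spectrum
    n_selected: int

    def reconstruct(self, windows: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(windows) - self.mean
        out = x @ self.components.T @ self.components + self.mean
        return out if np.ndim(windows) > 1 else out[0]


@dataclass(frozen=True)
class ShapeDictionary:
    prototypes: np.ndarray  # (k, d) centroids in processed-window space
    labels: tuple[str, ...]
    dispersions: np.ndarray  # (k, d) per-cluster per-sample standard deviation
    k: int
    pca: PcaBasis | None = None


def pca_reduce(windows: np.ndarray, variance_target: float = 0.98):
    """Project windows onto the minimal leading-component basis reaching
    ``variance_target`` cumulative explained variance, and reconstruct.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 windows")
    if not 0.0 < variance_target <= 1.0:
        raise InvalidArgumentError("variance_target must be in (0, 1]")
    pca = PCA(svd_solver="full").fit(windows)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    n_sel = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_sel = min(n_sel, len(ratios))
    basis = PcaBasis(pca.components_[:n_sel].copy(), pca.mean_.copy(),
                     ratios.copy(), n_sel)
    return basis, basis.reconstruct(windows)


def _fit_kmeans(windows: np.ndarray, k: int, seed) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, random_state=_as_int_seed(seed)).fit(windows)


def _as_int_seed(seed) -> int | None:
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    return int(np.random.default_rng(seed).integers(2 ** 31))


def choose_k(windows: np.ndarray, k_candidates, seed=None) -> int:
    """Consensus cluster count over silhouette and Calinski-Harabasz.

    Each index votes for its best k; the modal vote wins, ties toward the
    smaller k.  If even the best silhouette is below ``DEGENERATE_SILHOUETTE``
    the data has no cluster structure: the minimum candidate is returned
    with a logged warning.
    """
    windows = np.asarray(windows, dtype=float)
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise InvalidArgumentError("k_candidates must be non-empty")
    if ks[0] < 2 or ks[-1] > len(windows) - 1:
        raise InvalidArgumentError("k_candidates must lie within [2, n_windows - 1]")
    sil, ch = {}, {}
    for k in ks:
        km = _fit_kmeans(windows, k, seed)
        if len(np.unique(km.labels_)) < 2:
            sil[k], ch[k] = -1.0, 0.0
            continue
        sil[k] = silhouette_score(windows, km.labels_)
        ch[k] = calinski_harabasz_score(windows, km.labels_)
    if max(sil.values()) < DEGENERATE_SILHOUETTE:
        log.warning("no cluster structure (max silhouette %.3f); returning k=%d",
                    max(sil.values()), ks[0])
        return ks[0]
    votes = [min(k for k in ks if sil[k] == max(sil.values())),
             min(k for k in ks if ch[k] == max(ch.values()))]
    counts = Counter(votes)
    top = max(counts.values())
    return min(k for k, c in counts.items() if c == top)


def fit_dictionary(windows: np.ndarray, k: int, seed=None,
                   pca: PcaBasis | None = None) -> ShapeDictionary:
    """k-means prototypes over (reconstructed) windows.

    10 restarts with a fixed seed stream, best inertia kept.  Labels A, B,
    ... are assigned by decreasing cluster size (centroid norm breaks
    ties), so the labelling is deterministic given the seed.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2:
        raise InvalidArgumentError("windows must be 2-D")
    if not 1 <= k <= len(windows):
        raise InvalidArgumentError("k must be in [1, n_windows]")
    if k > len(string.ascii_uppercase):
        raise InvalidArgumentError("at most 26 prototypes supported")
    km = _fit_kmeans(windows, k, seed)
    sizes = np.bincount(km.labels_, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], -norms[c]))
    prototypes = km.cluster_centers_[order]
    dispersions = np.zeros_like(prototypes)
    for new_c, old_c in enumerate(order):
        members = windows[km.labels_ == old_c]
        if len(members):
            dispersions[new_c] = members.std(axis=0)
    return ShapeDictionary(prototypes, tuple(string.ascii_uppercase[:k]),
                           dispersions, k, pca=pca)


def label_event(processed_window: np.ndarray, dictionary: ShapeDictionary) -> str:
    """Label of the Euclidean-nearest prototype (ties to the lowest index).

    The window is passed through the dictionary's PCA reconstruction first,
    so distances are measured in the same denoised space the prototypes
    live in.
    """
    w = np.asarray(processed_window, dtype=float)
    if w.shape != dictionary.prototypes.shape[1:]:
        raise InvalidArgumentError("window length does not match prototypes")
    if dictionary.pca is not None:
        w = dictionary.pca.reconstruct(w)
    d = np.linalg.norm(dictionary.prototypes - w, axis=1)
    return dictionary.labels[int(np.argmin(d))]
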