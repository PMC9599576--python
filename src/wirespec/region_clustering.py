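"""Stage 2: Random-Forest-guided K-means++ region mapping.

The unlabeled line-scan spectra are clustered with K-means++ (cluster
count chosen by the silhouette coefficient), a Random Forest learns the
cluster labels and ranks the importance of each wavenumber, the two
most important bands are extracted, and the spectra are re-clustered on
those two band areas to call protein-rich vs nucleic-acid-rich regions.
The silhouette coefficient is

    SC = (1/N) * sum_i (b_i - a_i) / max(a_i, b_i)

with a_i the mean distance of sample i to the other members of its own
cluster and b_i the smallest mean distance to the members of any other
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .sers_metrics import BandWindow, band_area
from .spectra_core import SpectrumSet, WavenumberGrid

__all__ = [
    "ClusterResult",
    "ImportanceProfile",
    "kmeans_pp",
    "silhouette",
    "select_k_by_silhouette",
    "rf_importance",
    "smooth_importance",
    "top_bands",
    "extract_band_features",
    "classify_regions",
]

PROTEIN_RICH = "protein_rich"
NUCLEIC_ACID_RICH = "nucleic_acid_rich"


@dataclass
class ClusterResult:
    """Outcome of one clustering run.

    ``distance`` is each sample's Euclidean distance to its own cluster
    center; ``normalized_intensity`` rescales it within each cluster so
    the sample at the center scores 1 and the farthest sample 0.
    ``sc``, ``a`` and ``b`` carry the silhouette coefficient and its
    per-sample terms; ``n`` is the number of samples.
    """

    labels: np.ndarray
    centers: np.ndarray
    distance: np.ndarray
    normalized_intensity: np.ndarray
    sc: float
    n: int
    a: np.ndarray
    b: np.ndarray
    inertia: float
    molecular_labels: np.ndarray | None = None  # set by classify_regions


def _normalized_intensity(
    labels: np.ndarray, distance: np.ndarray
) -> np.ndarray:
    out = np.empty_like(distance)
    for lab in np.unique(labels):
        mask = labels == lab
        dmax = distance[mask].max()
        out[mask] = 1.0 if dmax == 0 else 1.0 - distance[mask] / dmax
    return np.clip(out, 0.0, 1.0)


def silhouette(X: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Silhouette coefficient with per-sample terms.

    Returns ``(SC, a, b)``. Samples in singleton clusters contribute
    s_i = 0 (their ``a`` is set to 0). Requires at least two clusters.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = X.shape[0]
    # exact pairwise Euclidean distances (the x^2+y^2-2xy shortcut loses
    # precision against the brute-force oracle)
    dist = cdist(X, X)

    a = np.zeros(n)
    b = np.full(n, np.inf)
    masks = {lab: labels == lab for lab in uniq}
    sizes = {lab: int(m.sum()) for lab, m in masks.items()}
    for lab in uniq:
        mine = masks[lab]
        for i in np.nonzero(mine)[0]:
            if sizes[lab] > 1:
                a[i] = dist[i, mine].sum() / (sizes[lab] - 1)
            for other in uniq:
                if other == lab:
                    continue
                b[i] = min(b[i], dist[i, masks[other]].mean())
    s = np.zeros(n)
    for i in range(n):
        if sizes[labels[i]] > 1:
            s[i] = (b[i] - a[i]) / max(a[i], b[i])
    return float(s.mean()), a, b


def kmeans_pp(X: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """K-means++ seeding plus Lloyd iterations, best of ``n_init``
    restarts by within-cluster sum of squares; seeded and deterministic."""
    X = np.asarray(X, dtype=np.float64)
    if k < 2:
        raise ValueError("need k >= 2")
    if X.shape[0] < k:
        raise ValueError(f"n={X.shape[0]} samples but k={k} clusters requested")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(X)
    labels = km.labels_.astype(int)
    centers = km.cluster_centers_
    distance = np.linalg.norm(X - centers[labels], axis=1)
    sc, a, b = silhouette(X, labels)
    return ClusterResult(
        labels=labels,
        centers=centers,
        distance=distance,
        normalized_intensity=_normalized_intensity(labels, distance),
        sc=sc,
        n=X.shape[0],
        a=a,
        b=b,
        inertia=float(km.inertia_),
    )


def select_k_by_silhouette(
    X: np.ndarray, k_min: int = 2, k_max: int = 5, seed: int = 0
) -> int:
    """Pick the cluster count maximizing the silhouette coefficient.

    Candidate counts below 2 are skipped (the silhouette is undefined
    for one cluster); ties go to the smaller k.
    """
    X = np.asarray(X, dtype=np.float64)
    if k_max > X.shape[0] - 1:
        raise ValueError("k_max must be at most n-1")
    best_k, best_sc = None, -np.inf
    for k in range(max(2, k_min), k_max + 1):
        sc = kmeans_pp(X, k, seed=seed).sc
        if sc > best_sc:
            best_k, best_sc = k, sc
    if best_k is None:
        raise ValueError("empty candidate range")
    return best_k


@dataclass
class ImportanceProfile:
    """Per-wavenumber feature importance, optionally smoothed."""

    wavenumbers: np.ndarray
    importance: np.ndarray  # sums to 1
    smoothed: np.ndarray | None = None

    @property
    def curve(self) -> np.ndarray:
        """Smoothed curve if available, raw importances otherwise."""
        return self.importance if self.smoothed is None else self.smoothed


def rf_importance(
    X: np.ndarray,
    labels: np.ndarray,
    grid: WavenumberGrid,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceProfile:
    """Random-Forest mean-decrease-in-impurity importance per wavenumber.

    Trains a forest (``n_trees`` trees, unlimited depth, sqrt(p)
    features per split) on the spectra with the given cluster labels;
    importances are normalized to sum 1.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes for importance")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=None,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    ).fit(np.asarray(X, dtype=np.float64), labels)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return ImportanceProfile(wavenumbers=grid.values.copy(), importance=imp)


def smooth_importance(
    profile: ImportanceProfile, window: float = 15.0
) -> ImportanceProfile:
    """Boxcar-smooth the importance curve over ``window`` cm^-1.

    Uses reflective boundary handling so total mass is conserved and a
    constant profile is left unchanged.
    """
    spacing = float(np.median(np.diff(profile.wavenumbers)))
    if window < spacing:
        raise ValueError("window must be at least the grid spacing")
    size = max(1, int(round(window / spacing)))
    if size % 2 == 0:
        size += 1
    smoothed = uniform_filter1d(profile.importance, size=size, mode="reflect")
    return ImportanceProfile(
        wavenumbers=profile.wavenumbers,
        importance=profile.importance,
        smoothed=smoothed,
    )


def _local_maxima(curve: np.ndarray) -> np.ndarray:
    """Indices of local maxima, boundaries included, one index per
    plateau (its center point)."""
    padded = np.concatenate([[-np.inf], curve, [-np.inf]])
    idx = []
    i = 1
    while i <= curve.size:
        if padded[i] > padded[i - 1]:
            j = i
            while j < curve.size and padded[j + 1] == padded[i]:
                j += 1
            if padded[i] > padded[j + 1]:
                idx.append((i + j) // 2 - 1)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def top_bands(
    profile: ImportanceProfile, n_bands: int = 2, min_separation: float = 50.0
) -> np.ndarray:
    """Highest local maxima of the (smoothed) importance curve, chosen
    greedily with pairwise separation >= ``min_separation`` cm^-1."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    curve = profile.curve
    maxima = _local_maxima(curve)
    if maxima.size == 0:
        raise ValueError("importance curve has no local maxima")
    order = maxima[np.argsort(curve[maxima], kind="stable")[::-1]]
    chosen: list[float] = []
    for j in order:
        wn = float(profile.wavenumbers[j])
        if all(abs(wn - c) >= min_separation for c in chosen):
            chosen.append(wn)
        if len(chosen) == n_bands:
            break
    if len(chosen) < n_bands:
        raise ValueError(
            f"only {len(chosen)} separated maxima available, "
            f"{n_bands} requested"
        )
    return np.asarray(chosen)


def extract_band_features(
    spectra: SpectrumSet, bands, halfwidth: float = 5.0
) -> np.ndarray:
    """Per-spectrum integrated band area over center +- halfwidth for
    each requested band; returns an (n_spectra, n_bands) matrix."""
    bands = np.atleast_1d(np.asarray(bands, dtype=np.float64))
    lo, hi = spectra.grid.values[0], spectra.grid.values[-1]
    for wn in bands:
        if wn < lo or wn > hi:
            raise ValueError(f"band {wn} cm^-1 outside grid [{lo}, {hi}]")
    windows = [BandWindow(center=wn, halfwidth=halfwidth) for wn in bands]
    out = np.empty((spectra.n_spectra, bands.size))
    for i, row in enumerate(spectra.intensities):
        for j, win in enumerate(windows):
            out[i, j] = band_area(row, spectra.grid, win)
    return out


def classify_regions(
    features: np.ndarray,
    protein_band_index: int = 1,
    seed: int = 0,
) -> ClusterResult:
    """Two-cluster K-means++ on the two standardized band features.

    The cluster whose center has the larger coordinate on the protein
    band (column ``protein_band_index``) is labeled protein-rich, the
    other nucleic-acid-rich. Normalized intensity is 1 at the cluster
    center and 0 at the farthest member of each cluster.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != 2:
        raise ValueError("features must have exactly 2 columns")
    sd = features.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate features: a band has zero variance")
    Z = (features - features.mean(axis=0)) / sd
    result = kmeans_pp(Z, k=2, seed=seed)
    protein_cluster = int(np.argmax(result.centers[:, protein_band_index]))
    result.molecular_labels = np.where(
        result.labels == protein_cluster, PROTEIN_RICH, NUCLEIC_ACID_RICH
    ).astype(object)
    return result
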