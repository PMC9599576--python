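"""Stage 1: discrimination of culture models from labeled spectra.

PCA on the merged labeled spectra, 95% confidence ellipses in the
(PC1, PC2) score plane, a quadrant rule that reads model-characteristic
bands off the loading vectors, and KNN validation using the
root-mean-square distance between score pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra_core import SpectrumSet

__all__ = [
    "PCAResult",
    "EllipseSpec",
    "KeyBandReport",
    "fit_pca",
    "confidence_ellipse",
    "ellipses_overlap",
    "key_bands_from_loadings",
    "knn_rms_distance",
    "knn_fit_score",
]


@dataclass
class PCAResult:
    """Mean-centered PCA of a spectral matrix.

    ``loadings`` rows are unit vectors over wavenumbers (one per
    component); ``scores`` columns are the projections of each spectrum;
    ``explained_proportion`` are the per-component variance fractions.
    """

    mean: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    scores: np.ndarray  # (n_spectra, n_components)
    explained_proportion: np.ndarray
    wavenumbers: np.ndarray


def fit_pca(spectra: SpectrumSet, n_components: int = 2) -> PCAResult:
    """Fit mean-centered PCA via SVD.

    Sign convention: each loading vector is flipped so that its
    largest-magnitude entry is positive, which makes the decomposition
    deterministic.
    """
    X = spectra.intensities
    n, p = X.shape
    if n_components < 2:
        raise ValueError("need n_components >= 2")
    if n <= n_components:
        raise ValueError("need more spectra than components")
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0):
        raise ValueError("constant input matrix: PCA undefined")
    # SVD of centered data == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    loadings = Vt[:n_components]
    # deterministic orientation: largest-|entry| positive per component
    flips = np.empty(n_components)
    for i, vec in enumerate(loadings):
        flips[i] = 1.0 if vec[np.argmax(np.abs(vec))] >= 0 else -1.0
    loadings = loadings * flips[:, None]
    scores = Xc @ loadings.T
    return PCAResult(
        mean=mean,
        loadings=loadings,
        scores=scores,
        explained_proportion=var[:n_components] / total_var,
        wavenumbers=spectra.grid.values.copy(),
    )


@dataclass(frozen=True)
class EllipseSpec:
    """Confidence ellipse in the (PC1, PC2) score plane."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float  # orientation of the first semi-axis
    level: float

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])  # world -> ellipse frame
        local = (pts - np.asarray(self.center)) @ rot.T
        a, b = self.semi_axes
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0 + margin

    def boundary(self, n: int = 720) -> np.ndarray:
        """Points on the ellipse boundary."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        local = np.column_stack(
            [self.semi_axes[0] * np.cos(t), self.semi_axes[1] * np.sin(t)]
        )
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + np.asarray(self.center)


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Fit a confidence ellipse to (PC1, PC2) points.

    Semi-axes are ``sqrt(eigenvalue * q)`` where the eigenvalues come
    from the sample covariance and ``q`` is the chi-square quantile at
    ``level`` with 2 degrees of freedom.
    """
    pts = np.asarray(scores, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.min(eigvals) <= 0:
        raise ValueError("singular covariance: ellipse undefined")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    semi_axes = np.sqrt(eigvals * q)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi_axes[0]), float(semi_axes[1])),
        angle_rad=angle,
        level=level,
    )


def ellipses_overlap(
    a: EllipseSpec,
    b: EllipseSpec,
    n_boundary: int = 720,
    margin: float = 1e-9,
) -> bool:
    """True iff the ellipse interiors intersect.

    Decided by testing each center for containment in the other ellipse
    (covers nesting) and by dense boundary sampling.
    """
    if a.contains(np.asarray([b.center]), margin)[0]:
        return True
    if b.contains(np.asarray([a.center]), margin)[0]:
        return True
    if a.contains(b.boundary(n_boundary), margin).any():
        return True
    if b.contains(a.boundary(n_boundary), margin).any():
        return True
    return False


@dataclass
class KeyBandReport:
    """Model-characteristic wavenumbers read off the loading quadrants.

    Entries assigned to the 2D model have PC1 loading > 0 and PC2
    loading < 0; entries assigned to the 3D model the reverse.
    """

    bands_2d: list[tuple[float, float, float]]  # (wavenumber, pc1, pc2)
    bands_3d: list[tuple[float, float, float]]

    def wavenumbers(self, label: str) -> np.ndarray:
        entries = self.bands_2d if label == "2D" else self.bands_3d
        return np.array([e[0] for e in entries])


def key_bands_from_loadings(
    pca: PCAResult, magnitude_threshold: float = 0.5
) -> KeyBandReport:
    """Select model-characteristic wavenumbers by the quadrant rule.

    A wavenumber qualifies when both |PC1| and |PC2| loadings exceed
    ``magnitude_threshold`` times the maximum |loading| of the
    respective component. Qualifying wavenumbers with (PC1 > 0, PC2 < 0)
    go to the 2D list, (PC1 < 0, PC2 > 0) to the 3D list; other
    quadrants stay unassigned.
    """
    if pca.loadings.shape[0] < 2:
        raise ValueError("need at least 2 components")
    pc1, pc2 = pca.loadings[0], pca.loadings[1]
    thr1 = magnitude_threshold * np.max(np.abs(pc1))
    thr2 = magnitude_threshold * np.max(np.abs(pc2))
    qualify = (np.abs(pc1) > thr1) & (np.abs(pc2) > thr2)
    bands_2d, bands_3d = [], []
    for j in np.nonzero(qualify)[0]:
        entry = (float(pca.wavenumbers[j]), float(pc1[j]), float(pc2[j]))
        if pc1[j] > 0 and pc2[j] < 0:
            bands_2d.append(entry)
        elif pc1[j] < 0 and pc2[j] > 0:
            bands_3d.append(entry)
    return KeyBandReport(bands_2d=bands_2d, bands_3d=bands_3d)


def knn_rms_distance(p, q) -> float:
    """Root-mean-square difference of the (PC1, PC2) score pairs:
    ``sqrt(((p1-q1)^2 + (p2-q2)^2) / 2)``."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    return float(np.sqrt(((p - q) ** 2).mean()))


def _stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def knn_fit_score(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 11,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> float:
    """Train/test a KNN classifier on (PC1, PC2) scores.

    A seeded stratified split holds out ``1 - train_fraction`` of each
    class. Test points are classified by majority vote among the ``k``
    nearest training points under :func:`knn_rms_distance`; vote ties
    are broken by the nearer neighbor's label, then lexicographically.
    Returns the fraction of correctly classified test points.
    """
    scores = np.asarray(scores, dtype=np.float64)[:, :2]
    labels = np.asarray(labels, dtype=object)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores/labels length mismatch")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(labels, train_fraction, rng)
    if np.unique(labels[train_idx]).size < 2:
        raise ValueError("both classes must be present in the training split")
    if k > train_idx.size:
        raise ValueError(f"k={k} exceeds training-set size {train_idx.size}")

    train_pts, train_lab = scores[train_idx], labels[train_idx]
    # rms distance = euclidean / sqrt(2): same neighbor ordering
    correct = 0
    for i in test_idx:
        d = np.sqrt(((train_pts - scores[i]) ** 2).mean(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        votes: dict[object, int] = {}
        for j in order:
            votes[train_lab[j]] = votes.get(train_lab[j], 0) + 1
        top = max(votes.values())
        tied = sorted(lab for lab, c in votes.items() if c == top)
        if len(tied) == 1:
            pred = tied[0]
        else:
            # nearer neighbor among tied labels wins, then lexicographic
            pred = next(
                train_lab[j] for j in order if train_lab[j] in tied
            )
        if pred == labels[i]:
            correct += 1
    return correct / test_idx.size
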