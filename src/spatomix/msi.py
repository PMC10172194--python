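"""MSI spectral preprocessing and unsupervised structure discovery.

Covers the desk equivalents of the vendor processing chain: peak alignment
and deisotoping at a fixed Da tolerance, TIC normalization, probabilistic
latent semantic analysis (pLSA) of the pixel x peak matrix into spatial
tissue components, PCA, and data-driven segmentation (PCA + k-means with
optional modal smoothing).

pLSA treats the nonnegative intensity matrix as co-occurrence counts
n(pixel, peak) and fits the mixture P(pixel, peak) = sum_k P(k) P(pixel|k)
P(peak|k) by EM.  Intensities are converted to pseudo-counts by TIC
normalization followed by scaling the matrix total to pixels x 1000; EM is
valid for arbitrary nonnegative weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "MSICube",
    "PLSAModel",
    "SegmentationMap",
    "INSTRUMENT_PRESETS",
    "C13_DELTA_DA",
    "DEFAULT_MZ_TOLERANCE_DA",
    "align_peaks",
    "remove_isotopes",
    "tic_normalize",
    "fit_plsa",
    "segment_pixels",
    "pca_scores",
]

# MarkerView-style processing tolerance and the 13C isotope spacing.
DEFAULT_MZ_TOLERANCE_DA = 0.01
C13_DELTA_DA = 1.00336

# Instrument presets: pixel pitch and MS1 mass accuracy of the two imaging
# platforms (ambient ESI on an Orbitrap; MALDI on a TOF/TOF).
INSTRUMENT_PRESETS = {
    "orbitrap": {"pitch_um": 100.0, "ppm_tolerance": 5.0, "modality": "metabolite"},
    "maldi-tof": {"pitch_um": 50.0, "ppm_tolerance": 10.0, "modality": "lipid"},
}


@dataclass
class MSICube:
    """Pixel-grid peak-intensity cube.

    ``coords`` has columns ``row, col, x, y`` (one row per pixel, centers in
    um); ``mz_values`` is the strictly increasing aligned peak list (Da);
    ``intensities`` is pixels x peaks, nonnegative.  ``peak_names`` optionally
    carries ground-truth compound names for synthetic cubes.
    """

    coords: pd.DataFrame
    mz_values: np.ndarray
    intensities: np.ndarray
    pitch: float
    ion_mode: str = "positive"
    instrument: str = "orbitrap"
    peak_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, float)
        self.intensities = np.asarray(self.intensities, float)
        if np.any(np.diff(self.mz_values) <= 0):
            raise ValueError("mz_values must be strictly increasing")
        if self.intensities.shape != (len(self.coords), len(self.mz_values)):
            raise ValueError("intensity matrix shape does not match pixels x peaks")
        if self.intensities.min(initial=0.0) < 0:
            raise ValueError("negative intensities")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"unknown ion mode {self.ion_mode!r}")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def n_peaks(self) -> int:
        return len(self.mz_values)

    def pixel_centers(self) -> np.ndarray:
        return self.coords[["x", "y"]].to_numpy(float)

    def feature_ids(self) -> list[str]:
        if self.peak_names is not None:
            return list(self.peak_names)
        return [f"mz_{mz:.5f}" for mz in self.mz_values]

    def shape_2d(self) -> tuple[int, int]:
        return int(self.coords["row"].max()) + 1, int(self.coords["col"].max()) + 1

    def replace_intensities(self, intensities: np.ndarray, **meta) -> "MSICube":
        return MSICube(
            self.coords, self.mz_values, intensities, self.pitch, self.ion_mode,
            self.instrument, self.peak_names, {**self.meta, **meta},
        )


@dataclass
class PLSAModel:
    """Fitted pLSA decomposition.

    ``pi_k``: component weights P(k); ``theta_pixel``: pixels x K columns
    P(pixel|k); ``phi_peak``: peaks x K columns P(peak|k); each column sums
    to one.  ``loglik_trace`` is the EM log-likelihood per iteration
    (non-decreasing up to numerical noise).
    """

    K: int
    pi_k: np.ndarray
    theta_pixel: np.ndarray
    phi_peak: np.ndarray
    loglik_trace: np.ndarray
    seed: int
    converged: bool

    def component_images(self, cube: MSICube) -> np.ndarray:
        """K x (rows x cols) rasters of pixel-topic intensity P(pixel|k)P(k)."""
        n_rows, n_cols = cube.shape_2d()
        imgs = np.zeros((self.K, n_rows, n_cols))
        rr = cube.coords["row"].to_numpy(int)
        cc = cube.coords["col"].to_numpy(int)
        for k in range(self.K):
            imgs[k, rr, cc] = self.theta_pixel[:, k] * self.pi_k[k]
        return imgs


@dataclass
class SegmentationMap:
    """Per-pixel cluster labels aligned with an MSICube's pixel order."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.n_clusters:
            raise ValueError("labels out of [0, n_clusters)")

    def as_image(self, cube: MSICube) -> np.ndarray:
        n_rows, n_cols = cube.shape_2d()
        img = np.full((n_rows, n_cols), -1, int)
        img[cube.coords["row"].to_numpy(int), cube.coords["col"].to_numpy(int)] = self.labels
        return img


# ---------------------------------------------------------------------------
# spectral preprocessing


def _split_cluster(mzs: np.ndarray, tol: float) -> list[np.ndarray]:
    """Recursively split a sorted m/z cluster wider than tol at its largest gap."""
    if len(mzs) < 2 or mzs[-1] - mzs[0] <= tol:
        return [mzs]
    gaps = np.diff(mzs)
    cut = int(np.argmax(gaps)) + 1
    return _split_cluster(mzs[:cut], tol) + _split_cluster(mzs[cut:], tol)


def align_peaks(
    peak_lists: Sequence[tuple[np.ndarray, np.ndarray]],
    mz_tolerance_da: float = DEFAULT_MZ_TOLERANCE_DA,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Align per-spectrum peak lists onto a common m/z axis.

    Greedy single-linkage scan of the pooled, ascending m/z values: a new
    cluster starts where the gap to the previous value exceeds the
    tolerance; clusters still wider than the tolerance are split at their
    largest internal gap.  The aligned m/z of a cluster is the
    intensity-weighted mean of its members.

    Returns the aligned m/z array and, per input spectrum, the column index
    each original peak maps to.
    """
    if mz_tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    sizes = [len(np.asarray(mz)) for mz, _ in peak_lists]
    if sum(sizes) == 0:
        return np.array([]), [np.array([], int) for _ in peak_lists]
    all_mz = np.concatenate([np.asarray(mz, float) for mz, _ in peak_lists])
    all_int = np.concatenate([np.asarray(i, float) for _, i in peak_lists])
    order = np.argsort(all_mz, kind="stable")
    mz_sorted = all_mz[order]
    # single-linkage chains, then gap-splitting of over-wide chains
    breaks = np.flatnonzero(np.diff(mz_sorted) > mz_tolerance_da) + 1
    chains = np.split(np.arange(len(mz_sorted)), breaks)
    clusters: list[np.ndarray] = []
    for chain in chains:
        for part in _split_cluster(mz_sorted[chain], mz_tolerance_da):
            clusters.append(chain[: len(part)])
            chain = chain[len(part):]
    cluster_of = np.empty(len(mz_sorted), int)
    aligned = np.empty(len(clusters))
    for c, members in enumerate(clusters):
        w = all_int[order[members]]
        m = mz_sorted[members]
        aligned[c] = np.average(m, weights=w) if w.sum() > 0 else m.mean()
        cluster_of[members] = c
    rank = np.argsort(aligned, kind="stable")
    aligned = aligned[rank]
    remap = np.empty_like(rank)
    remap[rank] = np.arange(len(rank))
    col_of_orig = np.empty(len(all_mz), int)
    col_of_orig[order] = remap[cluster_of]
    mappings, start = [], 0
    for size in sizes:
        mappings.append(col_of_orig[start: start + size].copy())
        start += size
    return aligned, mappings


def remove_isotopes(
    mz_list: np.ndarray,
    intensities: np.ndarray,
    delta_da: float = C13_DELTA_DA,
    mz_tolerance_da: float = DEFAULT_MZ_TOLERANCE_DA,
) -> np.ndarray:
    """Boolean keep-mask after single-spacing deisotoping.

    A peak is removed iff a peak one isotope spacing below (within the
    tolerance) exists with strictly greater intensity — the putative
    monoisotopic parent.  The most intense peak of a spectrum can never be
    removed.
    """
    mz = np.asarray(mz_list, float)
    inten = np.asarray(intensities, float)
    keep = np.ones(len(mz), bool)
    for j in range(len(mz)):
        parent = np.abs(mz - (mz[j] - delta_da)) <= mz_tolerance_da
        if np.any(inten[parent] > inten[j]):
            keep[j] = False
    return keep


def tic_normalize(cube: MSICube) -> MSICube:
    """Scale each pixel spectrum so its TIC equals the cube-wide median TIC.

    All-zero pixels cannot be rescaled; they stay zero and are flagged in
    ``meta['zero_pixels']``.
    """
    tic = cube.intensities.sum(axis=1)
    nonzero = tic > 0
    if not nonzero.any():
        raise ValueError("invalid-input: all pixels have zero TIC")
    target = float(np.median(tic[nonzero]))
    scale = np.ones_like(tic)
    scale[nonzero] = target / tic[nonzero]
    return cube.replace_intensities(
        cube.intensities * scale[:, None],
        tic_target=target,
        zero_pixels=np.flatnonzero(~nonzero).tolist(),
    )


# ---------------------------------------------------------------------------
# decomposition and segmentation


def to_pseudocounts(cube: MSICube, counts_per_pixel: float = 1000.0) -> np.ndarray:
    """TIC-normalized intensities rescaled to total pixels x counts_per_pixel."""
    norm = tic_normalize(cube).intensities
    total = norm.sum()
    return norm * (cube.n_pixels * counts_per_pixel / total)


def fit_plsa(
    cube: MSICube,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PLSAModel:
    """Fit a K-component pLSA to the cube by EM.

    E-step: P(k|i,j) proportional to P(k) P(i|k) P(j|k).  M-step: P(i|k)
    proportional to sum_j n(i,j) P(k|i,j), symmetrically for P(j|k), and
    P(k) proportional to sum_ij n(i,j) P(k|i,j).  Stops when the relative
    log-likelihood change drops below ``tol`` or after ``max_iter``
    iterations.  Initialization is Dirichlet(1) from ``seed``.
    """
    if K < 1:
        raise ValueError("invalid-argument: K must be >= 1")
    if K > min(cube.n_pixels, cube.n_peaks):
        raise ValueError("invalid-argument: K exceeds min(n_pixels, n_peaks)")
    n = to_pseudocounts(cube)
    total = n.sum()
    rng = np.random.default_rng(seed)
    pk = np.full(K, 1.0 / K)
    theta = rng.dirichlet(np.ones(cube.n_pixels), size=K).T  # pixels x K
    phi = rng.dirichlet(np.ones(cube.n_peaks), size=K).T  # peaks x K
    eps = 1e-300
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        mix = (theta * pk) @ phi.T  # P(i,j) up to the model, pixels x peaks
        loglik = float(np.sum(n * np.log(mix + eps)))
        trace.append(loglik)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(loglik - prev) <= tol * abs(prev):
                converged = True
                break
        w = n / (mix + eps)
        s_theta = pk * theta * (w @ phi)  # pixels x K: sum_j n P(k|ij)
        s_phi = pk * phi * (w.T @ theta)  # peaks x K: sum_i n P(k|ij)
        col = s_theta.sum(axis=0)
        pk = col / total
        theta = s_theta / np.maximum(col, eps)
        phi = s_phi / np.maximum(s_phi.sum(axis=0), eps)
    return PLSAModel(K, pk, theta, phi, np.asarray(trace), seed, converged)


def pca_scores(matrix: np.ndarray, n_dims: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a rows x features matrix (columns mean-centered internally).

    Returns (scores, loadings, explained-variance fractions).  A constant
    matrix yields all-zero scores rather than an error.
    """
    x = np.asarray(matrix, float)
    if n_dims > min(x.shape):
        raise ValueError("n_dims exceeds matrix rank bound")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0):
        return (
            np.zeros((x.shape[0], n_dims)),
            np.zeros((n_dims, x.shape[1])),
            np.zeros(n_dims),
        )
    pca = PCA(n_components=n_dims, svd_solver="full")
    scores = pca.fit_transform(centered)
    return scores, pca.components_, pca.explained_variance_ratio_


def segment_pixels(
    cube: MSICube,
    n_clusters: int,
    n_pca_dims: int = 10,
    seed: int = 0,
    smooth: bool = False,
) -> SegmentationMap:
    """Data-driven segmentation: TIC-normalize, PCA, k-means, optional 3x3
    modal smoothing of the label raster.

    The vendor segmentation method is proprietary and undocumented; this
    PCA + k-means chain is the package's defined equivalent.
    """
    if n_clusters < 2:
        raise ValueError("invalid-argument: n_clusters must be >= 2")
    if n_clusters > cube.n_pixels:
        raise ValueError("invalid-argument: n_clusters exceeds pixel count")
    norm = tic_normalize(cube).intensities
    n_dims = min(n_pca_dims, min(norm.shape))
    scores, _, _ = pca_scores(norm, n_dims)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    if smooth:
        img = np.full(cube.shape_2d(), -1, int)
        rr = cube.coords["row"].to_numpy(int)
        cc = cube.coords["col"].to_numpy(int)
        img[rr, cc] = labels

        def modal(window: np.ndarray) -> int:
            vals = window[window >= 0].astype(int)
            if len(vals) == 0:
                return -1
            return int(np.bincount(vals).argmax())

        smoothed = ndimage.generic_filter(img, modal, size=3, mode="constant", cval=-1)
        labels = smoothed[rr, cc]
    return SegmentationMap(labels, n_clusters)
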