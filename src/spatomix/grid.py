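"""Visium-like spot grid, landmark registration, and profile extraction.

The spatial-transcriptomics capture area is modelled as a square lattice of
barcoded spots (default 100 um center-to-center spacing, 55 um spot
diameter, 6.5 x 6.5 mm extent).  Spots are labelled ``x{i}y{j}`` with the
top-left spot ``x1y1``, ``x2y1`` one spacing to the right and ``x1y2`` one
spacing down.  MSI pixel coordinates are brought into the spot frame by a
landmark-fitted affine transform, assigned to spots by a Voronoi or circular
footprint rule, and averaged into per-spot profiles.

Coordinate convention: origin at the top-left corner of the section,
x rightward, y downward, micrometres; labels are 1-based, internal indices
0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SpotGrid",
    "AffineTransform",
    "PixelAssignment",
    "SpotFeatureTable",
    "VISIUM_SPACING_UM",
    "VISIUM_DIAMETER_UM",
    "VISIUM_EXTENT_UM",
    "BARCODE_LENGTH",
    "make_spot_grid",
    "label_spots",
    "fit_landmark_transform",
    "map_pixels_to_spots",
    "extract_spot_profiles",
    "extract_region_profiles",
]

# Platform geometry of the spatial gene-expression slide.
VISIUM_SPACING_UM = 100.0
VISIUM_DIAMETER_UM = 55.0
VISIUM_EXTENT_UM = (6500.0, 6500.0)
BARCODE_LENGTH = 16
UMI_LENGTH = 12


@dataclass
class SpotGrid:
    """Square lattice of capture spots.

    ``spots`` has one row per spot with columns
    ``label, col_idx, row_idx, center_x, center_y, barcode`` sorted row-major
    (top-left first).
    """

    spots: pd.DataFrame
    spacing: float
    diameter: float
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        if self.diameter >= self.spacing:
            raise ValueError("invalid-geometry: spot diameter must be < spacing")
        if self.spots["label"].duplicated().any():
            raise ValueError("invalid-grid: duplicate spot labels")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def centers(self) -> np.ndarray:
        return self.spots[["center_x", "center_y"]].to_numpy(float)

    @property
    def labels(self) -> list[str]:
        return self.spots["label"].tolist()


@dataclass
class AffineTransform:
    """2D affine map ``p -> A @ p + t`` (micrometre units)."""

    linear: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, float).reshape(2, 2)
        self.translation = np.asarray(self.translation, float).reshape(2)
        if abs(np.linalg.det(self.linear)) <= 1e-9:
            raise ValueError("underdetermined-transform: linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2), np.zeros(2))


@dataclass
class PixelAssignment:
    """Maps each MSI pixel (by row order of the cube) to a spot label.

    ``spot_index`` holds the positional index into ``spot_labels`` or -1 for
    unassigned pixels.
    """

    spot_index: np.ndarray
    spot_labels: list[str]
    footprint_rule: str

    def __post_init__(self) -> None:
        if self.footprint_rule not in ("voronoi", "circle"):
            raise ValueError(f"unknown footprint rule {self.footprint_rule!r}")

    @property
    def n_assigned(self) -> int:
        return int((self.spot_index >= 0).sum())


@dataclass
class SpotFeatureTable:
    """Spots x features matrix with modality tags and region annotations.

    ``values`` is indexed by spot label; ``modalities`` maps each feature id
    to one of {gene, metabolite, lipid}.  ``region`` is an optional observed
    annotation; ``true_region`` carries the phantom's ground truth and exists
    only for synthetic data.  ``missing`` flags spots that received no signal
    (no MSI pixels, zero sequencing depth) — their rows are NaN, not zero.
    """

    values: pd.DataFrame
    modalities: pd.Series
    region: pd.Series | None = None
    true_region: pd.Series | None = None
    missing: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative values in feature table")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")

    @property
    def spot_labels(self) -> list[str]:
        return self.values.index.tolist()

    def subset_modality(self, modality: str) -> "SpotFeatureTable":
        cols = self.modalities.index[self.modalities == modality]
        return SpotFeatureTable(
            self.values[cols], self.modalities[cols], self.region,
            self.true_region, self.missing, dict(self.meta),
        )


_BASES = np.array(list("ACGT"))


def random_barcodes(n: int, rng: np.random.Generator, length: int = BARCODE_LENGTH) -> list[str]:
    """Unique random DNA barcodes, one per capture spot."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def make_spot_grid(
    extent_um: Sequence[float] = VISIUM_EXTENT_UM,
    spacing_um: float = VISIUM_SPACING_UM,
    diameter_um: float = VISIUM_DIAMETER_UM,
    seed: int = 0,
) -> SpotGrid:
    """Build the square spot lattice covering ``extent_um``.

    Spot centers sit at cell centers (spacing/2 + i*spacing); a 6.5 mm
    extent at 100 um spacing gives 65 columns x 65 rows = 4225 spots.
    """
    width, height = float(extent_um[0]), float(extent_um[1])
    if spacing_um <= 0 or diameter_um <= 0:
        raise ValueError("invalid-geometry: spacing and diameter must be positive")
    if diameter_um >= spacing_um:
        raise ValueError("invalid-geometry: diameter must be smaller than spacing")
    if width < spacing_um or height < spacing_um:
        raise ValueError("invalid-geometry: extent smaller than one spacing")
    n_cols = int(np.floor(width / spacing_um))
    n_rows = int(np.floor(height / spacing_um))
    jj, ii = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()  # row-major: j (row) slow, i (col) fast
    rng = np.random.default_rng(seed)
    spots = pd.DataFrame(
        {
            "label": [f"x{i + 1}y{j + 1}" for i, j in zip(ii, jj)],
            "col_idx": ii,
            "row_idx": jj,
            "center_x": spacing_um / 2 + ii * spacing_um,
            "center_y": spacing_um / 2 + jj * spacing_um,
            "barcode": random_barcodes(n_cols * n_rows, rng),
        }
    )
    return SpotGrid(spots, spacing_um, diameter_um, (width, height))


def label_spots(grid: SpotGrid) -> SpotGrid:
    """(Re)assign ``x{i}y{j}`` labels from spot geometry.

    The top-left spot becomes x1y1, its right neighbour (one spacing in x)
    x2y1 and its lower neighbour (one spacing in y) x1y2.
    """
    spots = grid.spots.copy()
    centers = spots[["center_x", "center_y"]].to_numpy(float)
    if len(np.unique(np.round(centers, 6), axis=0)) != len(centers):
        raise ValueError("invalid-grid: duplicate spot centers")
    x0, y0 = centers[:, 0].min(), centers[:, 1].min()
    ii = np.rint((centers[:, 0] - x0) / grid.spacing).astype(int)
    jj = np.rint((centers[:, 1] - y0) / grid.spacing).astype(int)
    spots["col_idx"], spots["row_idx"] = ii, jj
    spots["label"] = [f"x{i + 1}y{j + 1}" for i, j in zip(ii, jj)]
    spots = spots.sort_values(["row_idx", "col_idx"], ignore_index=True)
    return SpotGrid(spots, grid.spacing, grid.diameter, grid.extent)


def fit_landmark_transform(src_points: np.ndarray, dst_points: np.ndarray) -> AffineTransform:
    """Least-squares affine registration from >= 3 landmark pairs.

    Minimizes sum ||A p + t - q||^2 over the 6 affine parameters; reports
    the residual RMS (um).  Collinear landmarks leave the problem
    underdetermined and raise.
    """
    src = np.asarray(src_points, float).reshape(-1, 2)
    dst = np.asarray(dst_points, float).reshape(-1, 2)
    if src.shape != dst.shape or len(src) < 3:
        raise ValueError("underdetermined-transform: need >= 3 landmark pairs")
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("underdetermined-transform: landmarks are collinear")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    linear, translation = coef[:2].T, coef[2]
    fitted = src @ linear.T + translation
    rms = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    return AffineTransform(linear, translation, residual_rms=rms)


def map_pixels_to_spots(
    msi_cube,
    spot_grid: SpotGrid,
    transform: AffineTransform | None = None,
    footprint_rule: str = "voronoi",
) -> PixelAssignment:
    """Assign each MSI pixel to at most one spot in the spot frame.

    voronoi: nearest spot center (distance ties go to the lexicographically
    smaller spot label); every in-extent pixel is assigned.  circle: assigned
    only if the pixel center falls inside the 55-um capture disc, otherwise
    unassigned.  Out-of-extent pixels are always unassigned, never an error.
    """
    if footprint_rule not in ("voronoi", "circle"):
        raise ValueError(f"unknown footprint rule {footprint_rule!r}")
    transform = transform or AffineTransform.identity()
    pts = transform.apply(msi_cube.pixel_centers())
    centers = spot_grid.centers
    tree = cKDTree(centers)
    dist, idx = tree.query(pts, k=2)
    labels = np.asarray(spot_grid.labels)
    nearest = idx[:, 0].copy()
    # break exact distance ties toward the lexicographically smaller label
    tie = np.isclose(dist[:, 0], dist[:, 1], rtol=0.0, atol=1e-9)
    for p in np.flatnonzero(tie):
        a, b = idx[p]
        nearest[p] = min((labels[a], a), (labels[b], b))[1]
    if footprint_rule == "voronoi":
        width, height = spot_grid.extent
        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= width)
            & (pts[:, 1] >= 0) & (pts[:, 1] <= height)
        )
        spot_index = np.where(inside, nearest, -1)
    else:
        within = dist[:, 0] <= spot_grid.diameter / 2
        spot_index = np.where(within, nearest, -1)
    return PixelAssignment(spot_index.astype(int), labels.tolist(), footprint_rule)


def extract_spot_profiles(msi_cube, assignment: PixelAssignment) -> SpotFeatureTable:
    """Per-spot mean peak intensity over the pixels assigned to each spot.

    Spots with no assigned pixels are flagged missing and carry NaN, so that
    "no measurement" never masquerades as zero intensity.
    """
    if msi_cube.n_pixels == 0 or msi_cube.n_peaks == 0:
        raise ValueError("invalid-input: empty MSI cube")
    if len(assignment.spot_index) != msi_cube.n_pixels:
        raise ValueError("assignment does not match this cube's pixels")
    n_spots = len(assignment.spot_labels)
    sums = np.zeros((n_spots, msi_cube.n_peaks))
    counts = np.zeros(n_spots)
    assigned = assignment.spot_index >= 0
    np.add.at(sums, assignment.spot_index[assigned], msi_cube.intensities[assigned])
    np.add.at(counts, assignment.spot_index[assigned], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts[:, None]
    feature_ids = msi_cube.feature_ids()
    values = pd.DataFrame(means, index=assignment.spot_labels, columns=feature_ids)
    modality = "lipid" if msi_cube.instrument == "maldi-tof" else "metabolite"
    modalities = pd.Series(modality, index=feature_ids)
    missing = pd.Series(counts == 0, index=assignment.spot_labels)
    return SpotFeatureTable(
        values, modalities, missing=missing,
        meta={"pixel_counts": counts.tolist(), "source_instrument": msi_cube.instrument},
    )


def extract_region_profiles(
    table_or_matrix, region_labels: Sequence
) -> tuple[pd.DataFrame, pd.Series]:
    """Average features within each labelled region.

    Accepts a SpotFeatureTable (rows = spots) or any 2D frame/array whose
    rows align with ``region_labels``.  Returns (region x feature mean
    matrix, per-region sample counts); regions with zero members are dropped
    with a warning, and NaN rows (missing spots) are excluded from means.
    """
    if isinstance(table_or_matrix, SpotFeatureTable):
        frame = table_or_matrix.values
    elif isinstance(table_or_matrix, pd.DataFrame):
        frame = table_or_matrix
    else:
        frame = pd.DataFrame(np.asarray(table_or_matrix, float))
    labels = pd.Series(list(region_labels), index=frame.index, name="region")
    if len(labels) != len(frame):
        raise ValueError("region labels do not cover the rows being aggregated")
    valid = ~frame.isna().all(axis=1)
    dropped = sorted(set(labels[~valid]) - set(labels[valid]))
    grouped = frame[valid].groupby(labels[valid], observed=True)
    means = grouped.mean()
    counts = grouped.size()
    if dropped:
        warnings.warn(f"regions with zero members excluded: {dropped}", stacklevel=2)
    return means, counts
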