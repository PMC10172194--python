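"""Serialization: 10x-style Matrix Market triplets, long-CSV MSI cubes,
raster images, transforms and manifests.

All writers are deterministic (fixed column orders, fixed float formats,
sorted JSON keys) so a re-run with identical seeds is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .grid import AffineTransform, PixelAssignment, SpotFeatureTable, SpotGrid
from .msi import MSICube
from .phantom import RegionImage

__all__ = [
    "write_st_counts",
    "read_st_counts",
    "write_msi_cube_csv",
    "read_msi_cube_csv",
    "write_msi_cube_imzml",
    "write_region_image",
    "read_region_image",
    "write_spot_grid",
    "read_spot_grid",
    "write_assignment",
    "write_transform",
    "read_transform",
    "dump_json",
]


def dump_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# spot x feature tables (10x triplet dialect)


def write_st_counts(
    table: SpotFeatureTable, outdir: str | Path, grid: SpotGrid | None = None
) -> dict[str, Path]:
    """Write matrix.mtx + barcodes.tsv + features.tsv (+ spots.tsv).

    The matrix is features x spots as in the 10x dialect.  barcodes.tsv has
    one barcode per spot (from the grid when given, else the spot label);
    features.tsv has id, name, modality; spots.tsv keeps the spot label,
    barcode and ground-truth region for the synthetic data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    values = table.values
    mat = sparse.csc_matrix(np.nan_to_num(values.to_numpy(float)).T)
    if np.allclose(mat.data, np.round(mat.data)):
        mat = mat.astype(np.int64)
    mtx = outdir / "matrix.mtx"
    spio.mmwrite(str(mtx), mat)
    if grid is not None:
        barcodes = grid.spots.set_index("label").loc[values.index, "barcode"]
    else:
        barcodes = pd.Series(values.index, index=values.index)
    bc_path = outdir / "barcodes.tsv"
    barcodes.to_csv(bc_path, sep="\t", index=False, header=False)
    feats = pd.DataFrame(
        {
            "id": values.columns,
            "name": values.columns,
            "modality": table.modalities.loc[values.columns].to_numpy(),
        }
    )
    ft_path = outdir / "features.tsv"
    feats.to_csv(ft_path, sep="\t", index=False, header=False)
    spots = pd.DataFrame({"label": values.index, "barcode": barcodes.to_numpy()})
    if table.true_region is not None:
        spots["true_region"] = table.true_region.loc[values.index].to_numpy()
    sp_path = outdir / "spots.tsv"
    spots.to_csv(sp_path, sep="\t", index=False)
    return {"matrix": mtx, "barcodes": bc_path, "features": ft_path, "spots": sp_path}


def read_st_counts(outdir: str | Path) -> SpotFeatureTable:
    outdir = Path(outdir)
    mat = spio.mmread(str(outdir / "matrix.mtx")).toarray().T
    feats = pd.read_csv(
        outdir / "features.tsv", sep="\t", header=None,
        names=["id", "name", "modality"],
    )
    spots = pd.read_csv(outdir / "spots.tsv", sep="\t")
    values = pd.DataFrame(mat, index=spots["label"], columns=feats["id"])
    true_region = (
        pd.Series(spots["true_region"].to_numpy(), index=spots["label"])
        if "true_region" in spots
        else None
    )
    return SpotFeatureTable(
        values,
        pd.Series(feats["modality"].to_numpy(), index=feats["id"]),
        true_region=true_region,
    )


# ---------------------------------------------------------------------------
# MSI cubes


def write_msi_cube_csv(cube: MSICube, path: str | Path) -> Path:
    """Long-format CSV: pixel_row, pixel_col, mz, intensity."""
    path = Path(path)
    n_pix, n_peak = cube.intensities.shape
    rows = np.repeat(cube.coords["row"].to_numpy(int), n_peak)
    cols = np.repeat(cube.coords["col"].to_numpy(int), n_peak)
    mz = np.tile(cube.mz_values, n_pix)
    long = pd.DataFrame(
        {
            "pixel_row": rows,
            "pixel_col": cols,
            "mz": mz,
            "intensity": cube.intensities.ravel(),
        }
    )
    long.to_csv(path, index=False, float_format="%.10g")
    meta = dict(cube.meta)
    meta.pop("true_region", None)
    dump_json(
        {
            "pitch_um": cube.pitch,
            "ion_mode": cube.ion_mode,
            "instrument": cube.instrument,
            "peak_names": cube.feature_ids(),
            **{f"meta_{k}": v for k, v in meta.items()},
        },
        path.with_suffix(".json"),
    )
    return path


def read_msi_cube_csv(path: str | Path) -> MSICube:
    path = Path(path)
    long = pd.read_csv(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    mz = np.sort(long["mz"].unique())
    pivot = long.pivot_table(
        index=["pixel_row", "pixel_col"], columns="mz", values="intensity", sort=True
    )
    pivot = pivot.reindex(columns=mz)
    rc = pivot.index.to_frame(index=False)
    pitch = float(meta["pitch_um"])
    coords = pd.DataFrame(
        {
            "row": rc["pixel_row"].to_numpy(int),
            "col": rc["pixel_col"].to_numpy(int),
            "x": pitch / 2 + rc["pixel_col"].to_numpy(int) * pitch,
            "y": pitch / 2 + rc["pixel_row"].to_numpy(int) * pitch,
        }
    )
    return MSICube(
        coords, mz, pivot.to_numpy(float), pitch,
        meta["ion_mode"], meta["instrument"],
        peak_names=meta.get("peak_names"),
        meta={k[5:]: v for k, v in meta.items() if k.startswith("meta_")},
    )


def write_msi_cube_imzml(cube: MSICube, path: str | Path) -> Path:
    """Continuous-mode imzML export (writes .imzML + binary .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(str(path.with_suffix("")), mode="continuous") as writer:
        for i in range(cube.n_pixels):
            writer.addSpectrum(
                cube.mz_values,
                cube.intensities[i],
                (int(cube.coords["col"].iat[i]) + 1, int(cube.coords["row"].iat[i]) + 1, 1),
            )
    return path


# ---------------------------------------------------------------------------
# rasters, grids, transforms


def write_region_image(image: RegionImage, path: str | Path) -> Path:
    """CSV raster of labels with a sidecar JSON of names and pixel size."""
    path = Path(path)
    np.savetxt(path, image.labels, fmt="%d", delimiter=",")
    dump_json(
        {"pixel_size_um": image.pixel_size, "region_names": image.region_names},
        path.with_suffix(".json"),
    )
    return path


def read_region_image(path: str | Path) -> RegionImage:
    path = Path(path)
    labels = np.loadtxt(path, dtype=int, delimiter=",", ndmin=2)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return RegionImage(labels, float(meta["pixel_size_um"]), meta["region_names"])


def write_spot_grid(grid: SpotGrid, path: str | Path) -> Path:
    path = Path(path)
    grid.spots.to_csv(path, sep="\t", index=False, float_format="%.10g")
    dump_json(
        {"spacing_um": grid.spacing, "diameter_um": grid.diameter,
         "extent_um": list(grid.extent)},
        path.with_suffix(".json"),
    )
    return path


def read_spot_grid(path: str | Path) -> SpotGrid:
    path = Path(path)
    spots = pd.read_csv(path, sep="\t")
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return SpotGrid(
        spots, float(meta["spacing_um"]), float(meta["diameter_um"]),
        tuple(meta["extent_um"]),
    )


def write_assignment(assignment: PixelAssignment, path: str | Path) -> Path:
    path = Path(path)
    labels = np.array(assignment.spot_labels + ["unassigned"])
    pd.DataFrame(
        {
            "pixel_index": np.arange(len(assignment.spot_index)),
            "spot_label": labels[assignment.spot_index],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_transform(transform: AffineTransform, path: str | Path) -> Path:
    """Six-number JSON: [a11, a12, a21, a22, tx, ty]."""
    return dump_json(
        {
            "affine": [*transform.linear.ravel().tolist(),
                       *transform.translation.tolist()],
            "residual_rms_um": transform.residual_rms,
        },
        path,
    )


def read_transform(path: str | Path) -> AffineTransform:
    with open(path) as fh:
        doc = json.load(fh)
    a = doc["affine"]
    return AffineTransform(
        np.array(a[:4]).reshape(2, 2), np.array(a[4:6]),
        residual_rms=float(doc.get("residual_rms_um", 0.0)),
    )
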