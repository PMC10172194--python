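"""MS1 accurate-mass annotation and marker-based cell-type calls.

Metabolite/lipid peaks are annotated by matching query m/z values against
theoretical adduct m/z computed from fixture monoisotopic masses, at the
instrument's mass accuracy (Orbitrap 5 ppm, MALDI-TOF 10 ppm; "accuracy of
less than x ppm" is applied strictly).  Spatial-transcriptomics clusters
are annotated by the one-sided hypergeometric enrichment of their marker
genes in curated cell-type marker lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "ADDUCTS",
    "PPM_TOLERANCE",
    "DEFAULT_ADDUCTS",
    "annotate_mass",
    "annotate_clusters",
    "CellTypeCall",
]

# Adduct mass shifts (Da) for singly charged species, from CODATA proton /
# electron masses; the electron mass is included since the observed species
# is the ion (documented to 1e-5 Da).
_PROTON = 1.00727646688  # m(H) - m(e)
_ELECTRON = 0.00054857991
ADDUCTS: dict[str, dict[str, float]] = {
    "positive": {
        "[M+H]+": _PROTON,
        "[M+Na]+": 22.98976928 - _ELECTRON,
        "[M+K]+": 38.96370649 - _ELECTRON,
    },
    "negative": {
        "[M-H]-": -_PROTON,
        "[M+Cl]-": 34.96885268 + _ELECTRON,
    },
}
DEFAULT_ADDUCTS = {
    "positive": ["[M+H]+", "[M+Na]+", "[M+K]+"],
    "negative": ["[M-H]-", "[M+Cl]-"],
}
PPM_TOLERANCE = {"orbitrap": 5.0, "maldi-tof": 10.0}


def annotate_mass(
    query_mz: float,
    ion_mode: str = "positive",
    instrument: str = "orbitrap",
    compound_db: pd.DataFrame | None = None,
    adduct_set: list[str] | None = None,
    ppm_tolerance: float | None = None,
) -> pd.DataFrame:
    """Rank (compound, adduct) candidates within the instrument tolerance.

    Returns a DataFrame with columns ``compound, adduct, theoretical_mz,
    ppm_error, instrument`` sorted by \\|ppm_error\\| (ties by compound name,
    then adduct), empty if nothing matches.  Acceptance is strict:
    \\|ppm_error\\| < tolerance.
    """
    if query_mz <= 0:
        raise ValueError("invalid-argument: query m/z must be positive")
    if ion_mode not in ADDUCTS:
        raise ValueError(f"unknown ion mode {ion_mode!r}")
    if compound_db is None:
        from . import fixtures

        compound_db = fixtures.load_compounds()
    tol = PPM_TOLERANCE[instrument] if ppm_tolerance is None else ppm_tolerance
    adducts = adduct_set if adduct_set is not None else DEFAULT_ADDUCTS[ion_mode]
    names = compound_db["name"].to_numpy()
    masses = compound_db["monoisotopic_mass"].to_numpy(float)
    rows = []
    for adduct in adducts:
        theo = masses + ADDUCTS[ion_mode][adduct]
        ppm = 1e6 * (query_mz - theo) / theo
        for i in np.flatnonzero(np.abs(ppm) < tol):
            rows.append((names[i], adduct, theo[i], ppm[i], instrument))
    out = pd.DataFrame(
        rows, columns=["compound", "adduct", "theoretical_mz", "ppm_error", "instrument"]
    )
    if len(out):
        out = out.iloc[
            np.lexsort((out["adduct"], out["compound"], np.abs(out["ppm_error"])))
        ].reset_index(drop=True)
    return out


@dataclass
class CellTypeCall:
    """Best cell-type assignment for one spot cluster."""

    cluster: int | str
    cell_type: str
    overlap: int
    p_value: float
    supporting_markers: list[str]


def annotate_clusters(
    cluster_markers: dict,
    celltype_markers: pd.DataFrame,
    universe: set | list,
) -> list[CellTypeCall]:
    """Hypergeometric cell-type annotation of cluster marker sets.

    ``cluster_markers`` maps cluster id -> marker gene collection (already
    screened, e.g. log2FC > 1 and p < 0.01 vs the other clusters);
    ``celltype_markers`` is the fixture table with ``cell_type`` and
    ``marker_gene_ids``; ``universe`` is all genes in the count matrix.  Per
    cluster the cell type with the smallest one-sided enrichment p is
    called; ties report every tied type; clusters with no markers or no
    overlap with any type are called "unassigned" with p = 1.
    """
    uni = set(universe)
    N = len(uni)
    if N == 0:
        raise ValueError("invalid-argument: empty gene universe")
    type_sets = {
        row["cell_type"]: set(row["marker_gene_ids"]) & uni
        for _, row in celltype_markers.iterrows()
    }
    calls: list[CellTypeCall] = []
    for cluster in sorted(cluster_markers, key=str):
        markers = set(cluster_markers[cluster]) & uni
        n = len(markers)
        best: list[tuple[float, str, int, list[str]]] = []
        for cell_type in sorted(type_sets):
            K = len(type_sets[cell_type])
            if K == 0 or n == 0:
                continue
            overlap = markers & type_sets[cell_type]
            x = len(overlap)
            if x == 0:
                continue
            p = float(hypergeom.sf(x - 1, N, K, n))
            best.append((p, cell_type, x, sorted(overlap)))
        if not best:
            calls.append(CellTypeCall(cluster, "unassigned", 0, 1.0, []))
            continue
        best.sort(key=lambda t: (t[0], t[1]))
        p_min = best[0][0]
        for p, cell_type, x, genes in best:
            if p > p_min:
                break
            calls.append(CellTypeCall(cluster, cell_type, x, p, genes))
    return calls
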