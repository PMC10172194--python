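"""Packaged reference tables: compounds, pathways, cell-type markers.

The compound table carries molecular formulas and monoisotopic masses (Da)
for the metabolites and lipids the phantom simulates; the pathway table maps
pathway ids to member genes and metabolites; the marker table maps cell
types to curated marker genes.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_compounds", "load_pathways", "load_celltype_markers"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_compounds() -> pd.DataFrame:
    """Compound reference: name, formula, monoisotopic_mass (Da), compound_class."""
    df = _read("compounds.csv")
    if df["name"].duplicated().any():
        raise ValueError("duplicate compound names in fixture table")
    if (df["monoisotopic_mass"] <= 0).any():
        raise ValueError("non-positive monoisotopic mass in fixture table")
    return df


def load_pathways() -> pd.DataFrame:
    """Pathway reference with gene_ids / metabolite_ids as python lists."""
    df = _read("pathways.csv")
    for col in ("gene_ids", "metabolite_ids"):
        df[col] = df[col].map(lambda s: s.split(";"))
    return df


def load_celltype_markers() -> pd.DataFrame:
    """Cell-type marker reference with marker_gene_ids as python lists."""
    df = _read("celltype_markers.csv")
    df["marker_gene_ids"] = df["marker_gene_ids"].map(lambda s: s.split(";"))
    return df
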