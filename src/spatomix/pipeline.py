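"""End-to-end pipeline driver.

Runs simulate -> register -> extract -> decompose -> segment -> cluster ->
markers -> annotate -> enrich -> network on the synthetic phantom, writing
every stage's outputs plus a manifest of parameters, seeds and statuses to
the run directory.  Completed stages are skipped on resume (a ``.done``
marker plus a config hash guard); all writers are deterministic so two
fresh runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures, io as sio
from .annotate import annotate_clusters, annotate_mass
from .grid import (
    extract_region_profiles,
    extract_spot_profiles,
    fit_landmark_transform,
    map_pixels_to_spots,
)
from .markers import differential_features, markers_per_group, screen_markers
from .msi import fit_plsa, segment_pixels
from .network import build_association_network, export_sankey, ora_hypergeom
from .phantom import DEFAULT_SEED, default_phantom_bundle
from .st import build_snn_graph, cluster_graph, normalize_counts

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline", "STAGES"]

DEFAULT_CONFIG: dict = {
    "seed": DEFAULT_SEED,
    "st": {
        "target_sum": 1e4,
        "n_pcs": 20,
        "k_neighbors": 15,
        "resolution": 1.0,
    },
    "msi": {
        "plsa_components": 5,
        "plsa_max_iter": 500,
        "plsa_tol": 1e-6,
        "segmentation_clusters": 10,
        "n_pca_dims": 10,
        "smooth": False,
    },
    "markers": {
        "group": "tumor",
        "reference": "peritumoral_muscularis",
        "gene_network_rule": "genes_network",
        "gene_enrichment_rule": "genes_enrichment",
        "metabolite_rule": "metabolites_network",
        "cluster_rule": "cluster_markers",
        "metabolite_fc": None,
    },
    "network": {"weight": "abs_log2fc"},
}

STAGES = [
    "simulate", "register", "extract", "decompose", "segment",
    "cluster", "markers", "annotate", "enrich", "network",
]


def validate_config(config: dict | None) -> dict:
    """Merge onto the defaults; unknown keys raise a config error naming them."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    offending: list[str] = []

    def merge(dst: dict, src: dict, prefix: str) -> None:
        for key, val in src.items():
            if key not in dst:
                offending.append(prefix + key)
            elif isinstance(dst[key], dict) and isinstance(val, dict):
                merge(dst[key], val, prefix + key + ".")
            else:
                dst[key] = val

    merge(merged, config or {}, "")
    if offending:
        raise ValueError(f"config error: unknown keys {sorted(offending)}")
    return merged


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _screen_rule(preset_or_fc, fallback_preset: str):
    if preset_or_fc is None:
        return fallback_preset
    return {"fc": float(preset_or_fc)}


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "spatomix_run",
    seed: int | None = None,
    resume: bool = True,
) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest: dict = {"config": cfg, "config_hash": chash, "stages": {}}
    ctx: dict = {}

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    def done_marker(name: str) -> Path:
        return out / name / ".done"

    def record(name: str, status: str, outputs: list[Path], params: dict) -> None:
        manifest["stages"][name] = {
            "status": status,
            "outputs": sorted(str(p.relative_to(out)) for p in outputs),
            "params": params,
            "seed": cfg["seed"],
        }

    def run_stage(name: str, params: dict, compute, load) -> None:
        marker = done_marker(name)
        if resume and marker.exists() and marker.read_text().strip() == chash:
            load(stage_dir(name))
            record(name, "cached", [p for p in stage_dir(name).rglob("*")
                                    if p.is_file() and p.name != ".done"], params)
            return
        try:
            outputs = compute(stage_dir(name))
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        marker.write_text(chash + "\n")
        record(name, "completed", outputs, params)

    # ---- simulate -------------------------------------------------------
    def compute_simulate(d: Path) -> list[Path]:
        bundle = default_phantom_bundle(seed=cfg["seed"])
        ctx["bundle"] = bundle
        outputs = [sio.write_region_image(bundle["region_image"], d / "region_image.csv")]
        outputs.append((d / "region_image.json"))
        outputs.append(sio.write_spot_grid(bundle["spot_grid"], d / "spot_grid.tsv"))
        outputs.append(d / "spot_grid.json")
        st_files = sio.write_st_counts(
            bundle["st_counts"], d / "st_counts", bundle["spot_grid"]
        )
        outputs.extend(st_files.values())
        outputs.append(sio.write_msi_cube_csv(bundle["afadesi_cube"], d / "afadesi_cube.csv"))
        outputs.append(d / "afadesi_cube.json")
        outputs.append(sio.write_msi_cube_csv(bundle["maldi_cube"], d / "maldi_cube.csv"))
        outputs.append(d / "maldi_cube.json")
        for key in ("gene_programs", "metabolite_programs", "lipid_programs"):
            p = d / f"{key}.csv"
            bundle[key].to_csv(p, index=False, float_format="%.10g")
            outputs.append(p)
        return outputs

    def load_simulate(d: Path) -> None:
        bundle = {
            "region_image": sio.read_region_image(d / "region_image.csv"),
            "spot_grid": sio.read_spot_grid(d / "spot_grid.tsv"),
            "st_counts": sio.read_st_counts(d / "st_counts"),
            "afadesi_cube": sio.read_msi_cube_csv(d / "afadesi_cube.csv"),
            "maldi_cube": sio.read_msi_cube_csv(d / "maldi_cube.csv"),
        }
        for key in ("gene_programs", "metabolite_programs", "lipid_programs"):
            bundle[key] = pd.read_csv(d / f"{key}.csv")
        ctx["bundle"] = bundle

    run_stage("simulate", {"seed": cfg["seed"]}, compute_simulate, load_simulate)
    bundle = ctx["bundle"]

    # ---- register -------------------------------------------------------
    # The phantom's modalities share one physical frame, so landmarks taken
    # at the section corners and center fit (and verify) an identity map.
    def compute_register(d: Path) -> list[Path]:
        w, h = bundle["region_image"].extent_um
        src = np.array([[0, 0], [w, 0], [0, h], [w, h], [w / 2, h / 2]], float)
        transform = fit_landmark_transform(src, src)
        ctx["transform"] = transform
        return [sio.write_transform(transform, d / "transform.json")]

    def load_register(d: Path) -> None:
        ctx["transform"] = sio.read_transform(d / "transform.json")

    run_stage("register", {"landmarks": "section corners + center"},
              compute_register, load_register)

    # ---- extract --------------------------------------------------------
    def compute_extract(d: Path) -> list[Path]:
        outputs: list[Path] = []
        for tag, cube_key in (("metabolite", "afadesi_cube"), ("lipid", "maldi_cube")):
            cube = bundle[cube_key]
            assignment = map_pixels_to_spots(
                cube, bundle["spot_grid"], ctx["transform"], "voronoi"
            )
            profiles = extract_spot_profiles(cube, assignment)
            profiles.true_region = bundle["st_counts"].true_region
            ctx[f"{tag}_profiles"] = profiles
            outputs.append(sio.write_assignment(assignment, d / f"{tag}_assignment.tsv"))
            outputs.extend(
                sio.write_st_counts(profiles, d / f"{tag}_spot_profiles").values()
            )
            means, counts = extract_region_profiles(
                profiles, bundle["st_counts"].true_region
            )
            p = d / f"{tag}_region_profiles.csv"
            means.to_csv(p, float_format="%.10g")
            outputs.append(p)
        return outputs

    def load_extract(d: Path) -> None:
        for tag in ("metabolite", "lipid"):
            profiles = sio.read_st_counts(d / f"{tag}_spot_profiles")
            profiles.true_region = bundle["st_counts"].true_region
            ctx[f"{tag}_profiles"] = profiles

    run_stage("extract", {"footprint_rule": "voronoi"}, compute_extract, load_extract)

    # ---- decompose (pLSA) ----------------------------------------------
    mcfg = cfg["msi"]

    def compute_decompose(d: Path) -> list[Path]:
        outputs: list[Path] = []
        for tag, cube_key in (("metabolite", "afadesi_cube"), ("lipid", "maldi_cube")):
            cube = bundle[cube_key]
            model = fit_plsa(
                cube, mcfg["plsa_components"], seed=cfg["seed"],
                max_iter=mcfg["plsa_max_iter"], tol=mcfg["plsa_tol"],
            )
            ctx[f"{tag}_plsa"] = model
            phi = pd.DataFrame(
                model.phi_peak, index=cube.feature_ids(),
                columns=[f"component_{k + 1}" for k in range(model.K)],
            )
            p = d / f"{tag}_plsa_peaks.csv"
            phi.to_csv(p, float_format="%.10g")
            outputs.append(p)
            theta = pd.DataFrame(
                model.theta_pixel,
                columns=[f"component_{k + 1}" for k in range(model.K)],
            )
            p = d / f"{tag}_plsa_pixels.csv"
            theta.to_csv(p, index=False, float_format="%.10g")
            outputs.append(p)
            p = d / f"{tag}_plsa_summary.json"
            sio.dump_json(
                {
                    "K": model.K,
                    "pi_k": model.pi_k.tolist(),
                    "loglik_trace": model.loglik_trace.tolist(),
                    "converged": model.converged,
                },
                p,
            )
            outputs.append(p)
        return outputs

    run_stage("decompose", {"K": mcfg["plsa_components"]},
              compute_decompose, lambda d: None)

    # ---- segment --------------------------------------------------------
    def compute_segment(d: Path) -> list[Path]:
        outputs = []
        for tag, cube_key in (("metabolite", "afadesi_cube"), ("lipid", "maldi_cube")):
            cube = bundle[cube_key]
            seg = segment_pixels(
                cube, mcfg["segmentation_clusters"], mcfg["n_pca_dims"],
                seed=cfg["seed"], smooth=mcfg["smooth"],
            )
            ctx[f"{tag}_segmentation"] = seg
            p = d / f"{tag}_segmentation.csv"
            np.savetxt(p, seg.as_image(cube), fmt="%d", delimiter=",")
            outputs.append(p)
        return outputs

    run_stage("segment", {"n_clusters": mcfg["segmentation_clusters"]},
              compute_segment, lambda d: None)

    # ---- cluster (ST) ---------------------------------------------------
    scfg = cfg["st"]

    def compute_cluster(d: Path) -> list[Path]:
        normalized = normalize_counts(bundle["st_counts"], scfg["target_sum"])
        graph = build_snn_graph(normalized, scfg["n_pcs"], scfg["k_neighbors"])
        assignment = cluster_graph(graph, scfg["resolution"], seed=cfg["seed"])
        ctx["normalized"] = normalized
        ctx["clusters"] = assignment
        clusters = assignment.labels.rename("cluster").rename_axis("spot_label")
        p1 = d / "clusters.tsv"
        clusters.to_csv(p1, sep="\t")
        edges = nx_edge_table(graph.graph)
        p2 = d / "snn_edges.tsv"
        edges.to_csv(p2, sep="\t", index=False, float_format="%.10g")
        p3 = d / "clustering_summary.json"
        sio.dump_json(
            {"n_clusters": assignment.n_clusters,
             "modularity": assignment.modularity}, p3
        )
        return [p1, p2, p3]

    def load_cluster(d: Path) -> None:
        ctx["normalized"] = normalize_counts(bundle["st_counts"], scfg["target_sum"])
        clusters = pd.read_csv(d / "clusters.tsv", sep="\t", index_col="spot_label")
        with open(d / "clustering_summary.json") as fh:
            summary = json.load(fh)
        from .st import ClusterAssignment

        ctx["clusters"] = ClusterAssignment(
            clusters["cluster"], summary["n_clusters"], summary["modularity"]
        )

    run_stage("cluster", dict(scfg), compute_cluster, load_cluster)

    # ---- markers --------------------------------------------------------
    kcfg = cfg["markers"]

    def compute_markers(d: Path) -> list[Path]:
        regions = bundle["st_counts"].true_region
        group = regions.index[regions == kcfg["group"]]
        reference = regions.index[regions == kcfg["reference"]]
        outputs = []
        # t-tests on log-normalized values, fold changes on raw count means
        gene_rec = differential_features(
            ctx["normalized"].subset_modality("gene"), group, reference,
            group_name=kcfg["group"], reference_name=kcfg["reference"],
            fold_values=bundle["st_counts"].values,
        )
        ctx["gene_records"] = gene_rec
        p = d / "gene_markers_full.tsv"
        gene_rec.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        for rule_key, name in (
            ("gene_network_rule", "gene_markers_network"),
            ("gene_enrichment_rule", "gene_markers_enrichment"),
        ):
            screened = screen_markers(gene_rec, kcfg[rule_key])
            ctx[name] = screened
            p = d / f"{name}.tsv"
            screened.to_csv(p, sep="\t", index=False, float_format="%.10g")
            outputs.append(p)
        met_rule = _screen_rule(kcfg["metabolite_fc"], kcfg["metabolite_rule"])
        met_tables = []
        for tag in ("metabolite", "lipid"):
            profiles = ctx[f"{tag}_profiles"]
            ok = ~profiles.values.isna().any(axis=1)
            rec = differential_features(
                profiles.values[ok.to_numpy()],
                [s for s in group if ok.get(s, False)],
                [s for s in reference if ok.get(s, False)],
                group_name=kcfg["group"], reference_name=kcfg["reference"],
            )
            rec["modality"] = tag
            met_tables.append(rec)
        met_rec = pd.concat(met_tables, ignore_index=True)
        ctx["met_records"] = met_rec
        p = d / "metabolite_markers_full.tsv"
        met_rec.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        ctx["met_markers_network"] = screen_markers(met_rec, met_rule)
        p = d / "metabolite_markers_network.tsv"
        ctx["met_markers_network"].to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        cluster_markers = markers_per_group(
            ctx["normalized"].subset_modality("gene"),
            ctx["clusters"].labels, kcfg["cluster_rule"],
            fold_values=bundle["st_counts"].values,
        )
        ctx["cluster_markers"] = cluster_markers
        rows = [t.assign(cluster=c) for c, t in cluster_markers.items()]
        table = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["cluster"])
        )
        p = d / "cluster_markers.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        return outputs

    def load_markers(d: Path) -> None:
        ctx["gene_records"] = pd.read_csv(d / "gene_markers_full.tsv", sep="\t")
        ctx["gene_markers_network"] = pd.read_csv(
            d / "gene_markers_network.tsv", sep="\t"
        )
        ctx["gene_markers_enrichment"] = pd.read_csv(
            d / "gene_markers_enrichment.tsv", sep="\t"
        )
        ctx["met_markers_network"] = pd.read_csv(
            d / "metabolite_markers_network.tsv", sep="\t"
        )
        table = pd.read_csv(d / "cluster_markers.tsv", sep="\t")
        ctx["cluster_markers"] = {
            c: t.drop(columns="cluster") for c, t in table.groupby("cluster")
        } if len(table) else {}

    run_stage("markers", dict(kcfg), compute_markers, load_markers)

    # ---- annotate -------------------------------------------------------
    def compute_annotate(d: Path) -> list[Path]:
        outputs = []
        rows = []
        for cube_key in ("afadesi_cube", "maldi_cube"):
            cube = bundle[cube_key]
            for mz in cube.mz_values:
                cands = annotate_mass(
                    float(mz), cube.ion_mode, cube.instrument
                )
                for _, c in cands.iterrows():
                    rows.append(
                        (cube.instrument, mz, c["compound"], c["adduct"],
                         c["theoretical_mz"], c["ppm_error"])
                    )
        ann = pd.DataFrame(
            rows,
            columns=["instrument", "query_mz", "compound", "adduct",
                     "theoretical_mz", "ppm_error"],
        )
        ctx["annotations"] = ann
        p = d / "mass_annotations.tsv"
        ann.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        calls = annotate_clusters(
            {c: t["feature_id"].tolist() for c, t in ctx["cluster_markers"].items()},
            fixtures.load_celltype_markers(),
            bundle["st_counts"].values.columns,
        )
        calls_df = pd.DataFrame(
            [
                (c.cluster, c.cell_type, c.overlap, c.p_value,
                 ";".join(c.supporting_markers))
                for c in calls
            ],
            columns=["cluster", "cell_type", "overlap", "p_value", "markers"],
        )
        ctx["celltype_calls"] = calls_df
        p = d / "celltype_calls.tsv"
        calls_df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs.append(p)
        return outputs

    run_stage("annotate", {}, compute_annotate, lambda d: None)

    # ---- enrich ---------------------------------------------------------
    def compute_enrich(d: Path) -> list[Path]:
        pathways = fixtures.load_pathways()
        universe = set(bundle["st_counts"].values.columns)
        selected = set(ctx["gene_markers_enrichment"]["feature_id"]) & universe
        result = ora_hypergeom(
            selected, universe,
            {row["pathway_id"]: row["gene_ids"] for _, row in pathways.iterrows()},
        )
        ctx["enrichment"] = result
        p = d / "pathway_enrichment.tsv"
        result.to_csv(p, sep="\t", index=False, float_format="%.10g")
        return [p]

    def load_enrich(d: Path) -> None:
        ctx["enrichment"] = pd.read_csv(d / "pathway_enrichment.tsv", sep="\t")

    run_stage("enrich", {}, compute_enrich, load_enrich)

    # ---- network --------------------------------------------------------
    def compute_network(d: Path) -> list[Path]:
        net = build_association_network(
            ctx["gene_markers_network"], ctx["met_markers_network"],
            weight=cfg["network"]["weight"],
        )
        ctx["network"] = net
        files = export_sankey(net, d)
        return list(files.values())

    run_stage("network", dict(cfg["network"]), compute_network, lambda d: None)

    sio.dump_json(manifest, out / "manifest.json")
    return manifest


def nx_edge_table(graph) -> pd.DataFrame:
    """Deterministically sorted edge list of a weighted graph."""
    rows = [
        (str(u), str(v), float(d.get("weight", 1.0)))
        if str(u) <= str(v)
        else (str(v), str(u), float(d.get("weight", 1.0)))
        for u, v, d in graph.edges(data=True)
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
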