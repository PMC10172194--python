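"""Synthetic tissue phantom and matched multi-omics simulators.

The phantom emulates an annotated gastric-cancer section: a 2D raster of
contiguous, irregular histological regions (tumor, tumor+gland mixed,
normal epithelium, intestinal metaplasia, lymphoid follicle, muscularis
mucosa, peritumoral muscularis, lamina propria, blood-containing and
connective tissue), region-specific gene expression programs sampled as
negative-binomial spot counts on the Visium-like grid, and region-specific
metabolite/lipid intensity archetypes sampled as log-normal MSI cubes at
the 100 um (ambient-ESI) and 50 um (MALDI) pixel pitches.

Every simulator is deterministic for a fixed seed; planted effects are kept
as ground truth on the outputs so downstream stages are testable.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fixtures
from .annotate import ADDUCTS
from .grid import SpotFeatureTable, SpotGrid, make_spot_grid
from .msi import INSTRUMENT_PRESETS, MSICube

__all__ = [
    "RegionImage",
    "DEFAULT_SEED",
    "DEFAULT_REGION_SPEC",
    "BASELINE_REGION",
    "make_phantom",
    "default_gene_programs",
    "default_msi_programs",
    "simulate_st_counts",
    "simulate_msi_cube",
]

# Packaged seed used for all default fixtures.
DEFAULT_SEED = 20429

# One region per histological type annotated on the reference section,
# with plausible area fractions (fractions are a modelling choice; the
# annotation lists only the types).
DEFAULT_REGION_SPEC: dict[str, float] = {
    "tumor": 0.18,
    "tumor_gland_mixed": 0.10,
    "normal_epithelium": 0.10,
    "intestinal_metaplasia": 0.08,
    "lymphoid_follicle": 0.08,
    "muscularis_mucosa": 0.10,
    "peritumoral_muscularis": 0.12,
    "lamina_propria": 0.08,
    "blood_containing": 0.06,
    "connective": 0.10,
}

# Sentinel region id for baseline (region-independent) program rows.
BASELINE_REGION = -1


@dataclass
class RegionImage:
    """2D raster of integer region labels with physical pixel size (um).

    Origin at the top-left corner (0, 0) um; pixel centers at cell centers.
    """

    labels: np.ndarray
    pixel_size: float
    region_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if self.labels.ndim != 2 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a 2D raster of at least 1x1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.labels.min() < 0 or self.labels.max() >= len(self.region_names):
            raise ValueError("labels out of [0, n_regions)")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def extent_um(self) -> tuple[float, float]:
        h, w = self.labels.shape
        return w * self.pixel_size, h * self.pixel_size

    def area_fractions(self) -> np.ndarray:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_regions)
        return counts / self.labels.size

    def region_at(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Region label at physical coordinates (clipped to the raster)."""
        h, w = self.labels.shape
        cc = np.clip((np.asarray(x_um) / self.pixel_size).astype(int), 0, w - 1)
        rr = np.clip((np.asarray(y_um) / self.pixel_size).astype(int), 0, h - 1)
        return self.labels[rr, cc]


def make_phantom(
    width_um: float = 6500.0,
    height_um: float = 6500.0,
    pixel_um: float = 50.0,
    region_spec: dict[str, float] | None = None,
    seed: int = DEFAULT_SEED,
) -> RegionImage:
    """Grow a labelled tissue raster with contiguous, irregular regions.

    Region nuclei are placed by greedy max-min separation, then regions grow
    pixel by pixel from per-region frontiers ordered by jittered distance to
    the nucleus; growth is scheduled by remaining area quota so final area
    fractions match ``region_spec`` (every pixel ends labelled).
    """
    if width_um <= 0 or height_um <= 0 or pixel_um <= 0:
        raise ValueError("invalid-argument: dimensions must be positive")
    if width_um < 2 * pixel_um or height_um < 2 * pixel_um:
        raise ValueError("invalid-argument: extent must be at least 2 pixels")
    spec = dict(region_spec) if region_spec is not None else dict(DEFAULT_REGION_SPEC)
    if not spec:
        raise ValueError("invalid-argument: region_spec must name at least one region")
    names = list(spec)
    fracs = np.array([spec[n] for n in names], float)
    if (fracs <= 0).any():
        raise ValueError("invalid-argument: region fractions must be positive")
    fracs = fracs / fracs.sum()
    h = int(height_um // pixel_um)
    w = int(width_um // pixel_um)
    n_pix, n_reg = h * w, len(names)
    if n_reg > n_pix:
        raise ValueError("infeasible-spec: more regions than pixels")
    rng = np.random.default_rng(seed)
    if n_reg == 1:
        return RegionImage(np.zeros((h, w), int), pixel_um, names)

    # exact pixel quotas by largest remainder
    quota = np.floor(fracs * n_pix).astype(int)
    rem = n_pix - quota.sum()
    order = np.argsort(-(fracs * n_pix - quota), kind="stable")
    quota[order[:rem]] += 1

    # greedy max-min nucleus placement from a seeded candidate pool
    cand = rng.choice(n_pix, size=min(n_pix, 60 * n_reg), replace=False)
    cand_rc = np.column_stack(np.unravel_index(cand, (h, w))).astype(float)
    nuclei = [0]
    for _ in range(n_reg - 1):
        d = np.min(
            [np.hypot(*(cand_rc - cand_rc[i]).T) for i in nuclei], axis=0
        )
        nuclei.append(int(np.argmax(d)))
    nuclei_rc = cand_rc[nuclei]

    labels = np.full((h, w), -1, int)
    heaps: list[list] = [[] for _ in range(n_reg)]
    counter = 0

    def push(region: int, r: int, c: int) -> None:
        nonlocal counter
        d = np.hypot(r - nuclei_rc[region, 0], c - nuclei_rc[region, 1])
        prio = d * (1.0 + 0.6 * rng.random())  # jitter -> irregular boundaries
        heapq.heappush(heaps[region], (prio, counter, r, c))
        counter += 1

    for reg, (r, c) in enumerate(nuclei_rc.astype(int)):
        push(reg, r, c)
    assigned = np.zeros(n_reg, int)
    remaining = n_pix
    active = np.ones(n_reg, bool)
    while remaining > 0 and active.any():
        # grow the region furthest behind its quota in relative terms, so
        # all regions stay at similar completion and enclosure losses stay small
        deficit = np.where(active, (quota - assigned) / quota, -1.0)
        reg = int(np.argmax(deficit))
        if deficit[reg] <= 0:
            # quotas met but pixels remain (blocked regions): let any active
            # region keep growing
            reg = int(np.argmax(np.where(active, 1, -1)))
        grew = False
        while heaps[reg]:
            _, _, r, c = heapq.heappop(heaps[reg])
            if labels[r, c] >= 0:
                continue
            labels[r, c] = reg
            assigned[reg] += 1
            remaining -= 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] < 0:
                    push(reg, rr, cc)
            grew = True
            break
        if not grew:
            active[reg] = False
        elif assigned[reg] >= quota[reg] and not heaps[reg]:
            active[reg] = False
    if remaining > 0:  # unreachable pockets: attach to nearest labelled pixel
        from scipy import ndimage

        _, (ir, ic) = ndimage.distance_transform_edt(labels < 0, return_indices=True)
        labels = np.where(labels < 0, labels[ir, ic], labels)
    labels = _rebalance_quotas(labels, quota, n_reg)
    return RegionImage(labels, pixel_um, names)


def _rebalance_quotas(labels: np.ndarray, quota: np.ndarray, n_reg: int) -> np.ndarray:
    """Flip boundary pixels from over- to adjacent under-quota regions.

    Jittered growth lets regions engulf neighbours; this pass walks the
    region boundaries until every area deviates from its quota by at most
    max(1 pixel, 0.5% of the raster), keeping regions contiguous since only
    pixels adjacent to the gaining region move.
    """
    h, w = labels.shape
    tol = max(1, int(0.005 * labels.size))
    for _ in range(400):
        counts = np.bincount(labels.ravel(), minlength=n_reg)
        dev = counts - quota
        if np.abs(dev).max() <= tol:
            break
        moved = 0
        # deterministic scan: move boundary pixels down the deviation
        # gradient (through intermediate regions if needed)
        for r in range(h):
            for c in range(w):
                o = labels[r, c]
                if dev[o] <= 0:
                    continue
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    u = labels[rr, cc]
                    if dev[u] < dev[o] - 1:
                        labels[r, c] = u
                        dev[o] -= 1
                        dev[u] += 1
                        moved += 1
                        break
        if moved == 0:
            break
    return labels


# ---------------------------------------------------------------------------
# expression programs

PROGRAM_COLUMNS = ["region_id", "feature_id", "modality", "base_level", "log2_effect"]


def validate_programs(programs: pd.DataFrame) -> pd.DataFrame:
    missing = set(PROGRAM_COLUMNS) - set(programs.columns)
    if missing:
        raise ValueError(f"program table missing columns {sorted(missing)}")
    if (programs["base_level"] < 0).any():
        raise ValueError("base_level must be >= 0")
    if programs.duplicated(["region_id", "feature_id", "modality"]).any():
        raise ValueError("duplicate (region, feature, modality) program rows")
    return programs


# Genes from the two reprogrammed pathways, placed in the regions where the
# study observed their elevation (tumor, and for some also lymphoid tissue).
_PATHWAY_GENE_REGIONS = {
    "GLS": ["tumor", "lymphoid_follicle"],
    "GLUL": ["tumor", "lymphoid_follicle", "muscularis_mucosa"],
    "ASS1": ["tumor", "lymphoid_follicle"],
    "ALDH18A1": ["tumor", "lymphoid_follicle"],
    "PYCR1": ["tumor", "lymphoid_follicle"],
    "OAT": ["tumor"],
    "AGMAT": ["tumor"],
    "SMS": ["tumor"],
    "ODC1": ["tumor", "lymphoid_follicle"],
    "SRM": ["tumor", "lymphoid_follicle"],
    "ACACA": ["tumor"],
    "FASN": ["tumor"],
    "SCD": ["tumor"],
    "FADS2": ["lymphoid_follicle"],
    "ELOVL1": ["tumor", "lymphoid_follicle"],
    "CHKA": ["tumor"],
    "ETNK1": ["tumor"],
    "PLD1": ["tumor"],
    "LYPLA2": ["tumor"],
    "CPT1A": ["tumor"],
    "CRAT": ["tumor"],
}

# Cell types localized to their home regions; their markers become part of
# the region's program so cluster annotation is exercised end to end.
_CELLTYPE_REGIONS = {
    "Epithelial cell": "normal_epithelium",
    "Tumor epithelial cell": "tumor",
    "T cell": "lymphoid_follicle",
    "B cell": "lymphoid_follicle",
    "Fibroblast": "connective",
    "Smooth muscle cell": "muscularis_mucosa",
    "Endothelial cell": "blood_containing",
    "Erythrocyte": "blood_containing",
    "Plasma cell": "lamina_propria",
}


def default_gene_programs(
    n_genes: int = 2000,
    markers_per_region: int = 40,
    log2_effect: float = 2.0,
    seed: int = DEFAULT_SEED,
    region_names: list[str] | None = None,
) -> pd.DataFrame:
    """One distinct expression program per default histological region.

    The gene panel mixes biologically named genes (pathway members and
    cell-type markers, planted in the regions where the study reports them
    elevated) with anonymous filler genes; each region additionally gets
    ``markers_per_region`` anonymous marker genes at the planted log2 fold
    change, so every region has a recoverable transcriptional identity.
    """
    regions = region_names if region_names is not None else list(DEFAULT_REGION_SPEC)
    rng = np.random.default_rng(seed)
    named: list[str] = []
    for g in _PATHWAY_GENE_REGIONS:
        named.append(g)
    ct = fixtures.load_celltype_markers()
    for _, row in ct.iterrows():
        named.extend(row["marker_gene_ids"])
    # genes of the remaining fixture pathways enter at baseline only, so
    # enrichment has genuinely tested (not skipped) null pathways
    for _, row in fixtures.load_pathways().iterrows():
        named.extend(row["gene_ids"])
    named = list(dict.fromkeys(named))
    n_filler = n_genes - len(named)
    if n_filler < 0:
        raise ValueError("n_genes smaller than the named gene panel")
    genes = named + [f"G{i:05d}" for i in range(n_filler)]
    base = np.round(rng.lognormal(mean=0.0, sigma=0.8, size=n_genes), 4)
    rows: list[tuple] = [
        (BASELINE_REGION, g, "gene", float(b), 0.0) for g, b in zip(genes, base)
    ]
    base_of = dict(zip(genes, base))
    region_idx = {name: i for i, name in enumerate(regions)}

    def plant(gene: str, region: str, effect: float) -> None:
        if region in region_idx:
            rows.append(
                (region_idx[region], gene, "gene",
                 float(max(base_of[gene], 0.5)), float(effect))
            )

    for gene, homes in _PATHWAY_GENE_REGIONS.items():
        for region in homes:
            plant(gene, region, log2_effect)
    for _, row in ct.iterrows():
        region = _CELLTYPE_REGIONS.get(row["cell_type"])
        if region is None:
            continue
        for gene in row["marker_gene_ids"]:
            plant(gene, region, log2_effect)
    # anonymous region markers drawn from the filler pool, disjoint by region
    filler = [g for g in genes if g.startswith("G")]
    need = markers_per_region * len(regions)
    if need > len(filler):
        raise ValueError("not enough filler genes for the requested markers")
    picks = rng.choice(len(filler), size=need, replace=False)
    for r, region in enumerate(regions):
        for g_idx in picks[r * markers_per_region: (r + 1) * markers_per_region]:
            gene = filler[g_idx]
            rows.append(
                (region_idx[region], gene, "gene",
                 float(max(base_of[gene], 0.5)), float(log2_effect))
            )
    df = pd.DataFrame(rows, columns=PROGRAM_COLUMNS)
    return validate_programs(df.drop_duplicates(["region_id", "feature_id", "modality"]))


# Five intensity archetypes mirroring the five spatial components the MSI
# decomposition recovers: each archetype is a disjoint peak set elevated in
# one region group.
_ARCHETYPE_REGIONS: dict[str, list[str]] = {
    "archetype_1": ["intestinal_metaplasia", "tumor"],
    "archetype_2": ["connective"],
    "archetype_3": ["muscularis_mucosa"],
    "archetype_4": ["tumor_gland_mixed"],
    "archetype_5": ["blood_containing"],
}

# Biology-informed peak placement: the tumor-containing archetype carries
# the polyamines and arginine/proline intermediates (reported elevated in
# tumor tissue) and, on the lipid side, the de novo synthesis products;
# compounds not listed are distributed round-robin over the remaining
# archetypes.
_ARCHETYPE_COMPOUNDS: dict[str, dict[str, list[str]]] = {
    "metabolite": {
        "archetype_1": ["glutamate", "arginine", "proline", "ornithine",
                        "putrescine", "spermidine", "spermine", "lactic acid"],
        "archetype_2": ["glutamine", "taurine", "creatine"],
        "archetype_3": ["glucose", "glutathione"],
        "archetype_4": ["histamine", "carnitine"],
        "archetype_5": ["hypoxanthine", "inosine", "adenine"],
    },
    "lipid": {
        "archetype_1": ["palmitic acid", "stearic acid", "PC(34:1)"],
        "archetype_2": ["oleic acid", "PE(34:1)"],
        "archetype_3": ["linoleic acid", "PE(36:2)"],
        "archetype_4": ["arachidonic acid", "PC(36:2)", "docosatetraenoic acid"],
        "archetype_5": ["docosahexaenoic acid", "docosapentaenoic acid"],
    },
}


def default_msi_programs(
    modality: str = "metabolite",
    base_level: float = 20.0,
    log2_effect: float = 2.0,
    seed: int = DEFAULT_SEED,
    region_names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Region-specific metabolite (or lipid) archetypes over fixture compounds.

    Splits the fixture compounds of the modality into five disjoint peak
    sets (tumor-associated compounds pinned to the tumor-containing
    archetype, the rest round-robin); each set is elevated
    2^log2_effect-fold in its archetype's region group.  Returns the
    program table and the archetype -> compound map.
    """
    del seed  # assignment is fully deterministic
    regions = region_names if region_names is not None else list(DEFAULT_REGION_SPEC)
    comp = fixtures.load_compounds()
    lipid_classes = {"fatty acid", "glycerophospholipid"}
    is_lipid = comp["compound_class"].isin(lipid_classes)
    pool = comp[is_lipid if modality == "lipid" else ~is_lipid]["name"].tolist()
    arch_names = list(_ARCHETYPE_REGIONS)
    pinned = _ARCHETYPE_COMPOUNDS[modality]
    assignment: dict[str, list[str]] = {
        a: [c for c in pinned.get(a, []) if c in pool] for a in arch_names
    }
    placed = {c for members in assignment.values() for c in members}
    leftovers = [c for c in pool if c not in placed]
    for i, name in enumerate(leftovers):
        assignment[arch_names[i % len(arch_names)]].append(name)
    pool = [c for members in assignment.values() for c in members]
    region_idx = {name: i for i, name in enumerate(regions)}
    rows: list[tuple] = [
        (BASELINE_REGION, name, modality, base_level, 0.0) for name in pool
    ]
    for arch, members in assignment.items():
        for region in _ARCHETYPE_REGIONS[arch]:
            if region not in region_idx:
                continue
            for name in members:
                rows.append((region_idx[region], name, modality, base_level, log2_effect))
    df = pd.DataFrame(rows, columns=PROGRAM_COLUMNS)
    return validate_programs(df), assignment


def _mean_matrix(
    programs: pd.DataFrame, modality: str, n_regions: int
) -> tuple[list[str], np.ndarray]:
    """(features, regions x features mean matrix) from a program table."""
    sub = programs[programs["modality"] == modality]
    feats = list(dict.fromkeys(sub["feature_id"]))
    f_idx = {f: i for i, f in enumerate(feats)}
    means = np.zeros((n_regions, len(feats)))
    base = sub[sub["region_id"] == BASELINE_REGION]
    for _, row in base.iterrows():
        means[:, f_idx[row["feature_id"]]] = row["base_level"]
    for _, row in sub[sub["region_id"] != BASELINE_REGION].iterrows():
        r = int(row["region_id"])
        if not 0 <= r < n_regions:
            raise ValueError(f"program references unknown region {r}")
        means[r, f_idx[row["feature_id"]]] = row["base_level"] * 2.0 ** row["log2_effect"]
    return feats, means


# ---------------------------------------------------------------------------
# simulators


def spot_regions(region_image: RegionImage, spot_grid: SpotGrid) -> np.ndarray:
    """Majority region label under each spot's capture disc."""
    h, w = region_image.labels.shape
    ps = region_image.pixel_size
    radius = spot_grid.diameter / 2
    out = np.empty(spot_grid.n_spots, int)
    for s, (cx, cy) in enumerate(spot_grid.centers):
        c0 = max(int((cx - radius) / ps), 0)
        c1 = min(int((cx + radius) / ps) + 1, w)
        r0 = max(int((cy - radius) / ps), 0)
        r1 = min(int((cy + radius) / ps) + 1, h)
        patch = region_image.labels[r0:r1, c0:c1]
        if patch.size == 0:
            out[s] = region_image.region_at(np.array([cx]), np.array([cy]))[0]
        else:
            out[s] = np.bincount(patch.ravel()).argmax()
    return out


def simulate_st_counts(
    region_image: RegionImage,
    spot_grid: SpotGrid,
    programs: pd.DataFrame,
    dispersion: float = 2.0,
    depth: float = 1.0,
    seed: int = DEFAULT_SEED,
) -> SpotFeatureTable:
    """Negative-binomial spot x gene counts from region-specific programs.

    Counts for spot s and gene g are NB with mean depth * base_level *
    2^log2_effect of the program row for (region(s), g) and shape
    ``dispersion`` (variance mu + mu^2/dispersion; large dispersion
    approaches Poisson).  The spot's region is the majority region label
    under its capture footprint and is stored as ground truth.
    """
    if dispersion <= 0 or depth <= 0:
        raise ValueError("dispersion and depth must be positive")
    width, height = region_image.extent_um
    centers = spot_grid.centers
    outside = (
        (centers[:, 0] < 0) | (centers[:, 0] > width)
        | (centers[:, 1] < 0) | (centers[:, 1] > height)
    )
    if outside.any():
        bad = spot_grid.spots["label"].iloc[int(np.flatnonzero(outside)[0])]
        raise ValueError(f"spot {bad} lies outside the tissue raster")
    validate_programs(programs)
    genes, means = _mean_matrix(programs, "gene", region_image.n_regions)
    regions = spot_regions(region_image, spot_grid)
    mu = means[regions] * depth  # spots x genes
    rng = np.random.default_rng(seed)
    p = dispersion / (dispersion + mu)
    counts = np.zeros_like(mu, dtype=int)
    pos = mu > 0
    counts[pos] = rng.negative_binomial(dispersion, p[pos])
    labels = spot_grid.labels
    region_names = [region_image.region_names[r] for r in regions]
    values = pd.DataFrame(counts, index=labels, columns=genes)
    return SpotFeatureTable(
        values,
        pd.Series("gene", index=genes),
        true_region=pd.Series(region_names, index=labels),
        meta={"dispersion": dispersion, "depth": depth, "seed": seed,
              "umi_length": 12, "barcode_length": 16},
    )


def simulate_msi_cube(
    region_image: RegionImage,
    pitch_um: float,
    programs: pd.DataFrame,
    noise_sd: float = 1.0,
    baseline: float = 2.0,
    lognormal_sigma: float = 0.25,
    modality: str = "metabolite",
    ion_mode: str = "positive",
    adduct: str = "[M+H]+",
    seed: int = DEFAULT_SEED,
) -> MSICube:
    """Log-normal MSI peak cube on a pitch x pitch pixel lattice.

    Pixel intensity = LogNormal(median = programmed region mean, shape =
    ``lognormal_sigma``) + ``baseline`` + Gaussian(0, ``noise_sd``),
    truncated at zero; ``lognormal_sigma = 0`` and ``noise_sd = 0`` give
    exactly the programmed means plus baseline.  Peak m/z values are fixture
    compound masses plus the adduct mass; the instrument tag follows the
    pitch preset (100 um -> orbitrap, 50 um -> maldi-tof).
    """
    if pitch_um <= 0:
        raise ValueError("invalid-argument: pitch must be positive")
    if noise_sd < 0:
        raise ValueError("invalid-argument: noise_sd must be >= 0")
    width, height = region_image.extent_um
    n_cols, n_rows = int(width // pitch_um), int(height // pitch_um)
    if n_cols < 1 or n_rows < 1:
        raise ValueError("infeasible-spec: pitch larger than the raster extent")
    validate_programs(programs)
    feats, means = _mean_matrix(programs, modality, region_image.n_regions)
    comp = fixtures.load_compounds().set_index("name")
    unknown = [f for f in feats if f not in comp.index]
    if unknown:
        raise ValueError(f"program features missing from compound fixture: {unknown}")
    masses = comp.loc[feats, "monoisotopic_mass"].to_numpy(float)
    mz = masses + ADDUCTS[ion_mode][adduct]
    order = np.argsort(mz, kind="stable")
    mz, feats = mz[order], [feats[i] for i in order]
    means = means[:, order]
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    xs = pitch_um / 2 + cc * pitch_um
    ys = pitch_um / 2 + rr * pitch_um
    regions = region_image.region_at(xs, ys)
    mu = means[regions]  # pixels x peaks
    rng = np.random.default_rng(seed)
    if lognormal_sigma > 0:
        signal = np.where(
            mu > 0,
            rng.lognormal(np.log(np.maximum(mu, 1e-300)), lognormal_sigma),
            0.0,
        )
    else:
        signal = mu.copy()
    intensity = signal + baseline
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=mu.shape)
    intensity = np.maximum(intensity, 0.0)
    instrument = "maldi-tof" if np.isclose(pitch_um, 50.0) else "orbitrap"
    coords = pd.DataFrame({"row": rr, "col": cc, "x": xs, "y": ys})
    return MSICube(
        coords, mz, intensity, pitch_um, ion_mode, instrument,
        peak_names=feats,
        meta={
            "seed": seed, "noise_sd": noise_sd, "baseline": baseline,
            "lognormal_sigma": lognormal_sigma, "modality": modality,
            "adduct": adduct,
            "true_region": [region_image.region_names[r] for r in regions],
        },
    )


def default_phantom_bundle(seed: int = DEFAULT_SEED) -> dict:
    """The packaged study conditions: phantom, grid, ST counts, two cubes.

    Sub-seeds for each simulator are derived from ``seed`` so a single
    integer reproduces the full bundle.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    region_image = make_phantom(seed=sub[0])
    spot_grid = make_spot_grid(seed=sub[1])
    gene_programs = default_gene_programs(seed=seed)
    st_counts = simulate_st_counts(region_image, spot_grid, gene_programs, seed=sub[2])
    met_programs, met_arch = default_msi_programs("metabolite", seed=seed)
    lip_programs, lip_arch = default_msi_programs("lipid", seed=seed)
    afadesi = simulate_msi_cube(
        region_image, INSTRUMENT_PRESETS["orbitrap"]["pitch_um"], met_programs,
        modality="metabolite", seed=sub[3],
    )
    maldi = simulate_msi_cube(
        region_image, INSTRUMENT_PRESETS["maldi-tof"]["pitch_um"], lip_programs,
        modality="lipid", seed=sub[3] + 1,
    )
    return {
        "region_image": region_image,
        "spot_grid": spot_grid,
        "gene_programs": gene_programs,
        "st_counts": st_counts,
        "metabolite_programs": met_programs,
        "metabolite_archetypes": met_arch,
        "lipid_programs": lip_programs,
        "lipid_archetypes": lip_arch,
        "afadesi_cube": afadesi,
        "maldi_cube": maldi,
        "seed": seed,
    }
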