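"""End-to-end pipeline: simulate -> sites -> extract -> dissim -> mrm -> gdm -> map.

Each stage reads the artifacts of the previous stages from the output
directory, writes its own artifacts exactly once, and appends a line to
``manifest.jsonl`` recording input hashes, the configuration hash, the
stage seed and row counts.  Deterministic stages are bit-identical on
rerun; stochastic stages are identical given the same top-level seed.

All randomness flows from the single top-level seed: stage k uses
``SeedSequence(seed, spawn_key=(k,))``, so stages are independently and
reproducibly seeded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dissimilarity as dsm
from . import envtable, gdm, mrm, occurrences, raster, synth
from .mcl import MCLParams, cluster_sites

__all__ = ["RunConfig", "run_stage", "run_all", "STAGES", "fixture_config"]

STAGES = ["simulate", "sites", "extract", "dissim", "mrm", "gdm", "map"]


@dataclass
class RunConfig:
    """Structured configuration of a full run.

    Seeds are explicit (never wall-clock); the config round-trips
    through YAML unchanged.
    """

    out_dir: str = "results/run"
    seed: int = 0
    occurrences_path: str | None = None  # defaults to the simulated table
    # synthetic world
    extent: tuple[float, float, float, float] = synth.FIXTURE_CONFIG["extent"]
    grid_shape: tuple[int, int] = synth.FIXTURE_CONFIG["grid_shape"]
    n_env_vars: int = synth.FIXTURE_CONFIG["n_env_vars"]
    n_classes: int = synth.FIXTURE_CONFIG["n_classes"]
    n_species: int = synth.FIXTURE_CONFIG["n_species"]
    n_records: int = synth.FIXTURE_CONFIG["n_records"]
    effort_ratio: float = synth.FIXTURE_CONFIG["effort_ratio"]
    # site formation
    mcl: dict = field(
        default_factory=lambda: dict(
            inflation=2.0,
            pre_inflation=1.0,
            edge_radius=0.5,
            kernel_bandwidth=0.1,
            prune_threshold=1e-5,
        )
    )
    boundary_mode: str = "cell_corners"
    min_sites_per_species: int = 30
    min_obs_per_site: int = 300
    # statistics
    dissimilarity_variant: str = "horn"
    haversine: bool = False
    mrm_n_perm: int = 999
    gdm_n_splines: int = 3
    gdm_n_perm: int = 100
    gdm_alpha: float = 0.05

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("extent", "grid_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        k = STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(k,))
        return int(ss.generate_state(1)[0] % (2**31))


def fixture_config(out_dir: str, seed: int = 0) -> RunConfig:
    """The packaged small-world configuration used by the test suite.

    The sparsity thresholds are scaled to the fixture's data volume
    (20k records vs the tens of millions of a real snapshot): species
    must appear at >= 2 sites and sites must hold >= 3 records.  MCL
    edge radius/bandwidth are widened to the fixture's ~1-degree pixel
    scale so that sites aggregate a sensible number of records.
    """
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        min_sites_per_species=2,
        min_obs_per_site=3,
        mcl=dict(
            inflation=2.0,
            pre_inflation=1.0,
            edge_radius=0.8,
            kernel_bandwidth=0.3,
            prune_threshold=1e-4,
        ),
        mrm_n_perm=199,
        gdm_n_perm=20,
    )


# ---------------------------------------------------------------------
# manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_append(out: Path, entry: dict) -> None:
    with open(out / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")


def _require(out: Path, filename: str, produced_by: str) -> Path:
    p = out / filename
    if not p.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {filename!r}: run the {produced_by!r} stage first"
        )
    return p


def _entry(config: RunConfig, stage: str, inputs: list[Path], outputs: list[Path], **counts):
    return {
        "stage": stage,
        "seed": config.stage_seed(stage),
        "config_hash": config.config_hash(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
        "counts": counts,
    }


# ---------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    seed = config.stage_seed("simulate")
    world = synth.generate_world(
        extent=config.extent,
        grid_shape=tuple(config.grid_shape),
        n_env_vars=config.n_env_vars,
        n_classes=config.n_classes,
        seed=seed,
    )
    pool = synth.generate_species_pool(world, n_species=config.n_species, seed=seed + 1)
    effort = synth.two_patch_effort(world, ratio=config.effort_ratio)
    occ = synth.sample_occurrences(world, pool, effort, config.n_records, seed=seed + 2)
    outputs = []
    for name, grid in world.env_stack.items():
        p = out / f"env_{name}.asc"
        raster.write_ascii_grid(grid, p)
        outputs.append(p)
    p = out / "classes.asc"
    raster.write_ascii_grid(world.class_grid, p)
    outputs.append(p)
    p = out / "effort.asc"
    raster.write_ascii_grid(effort, p)
    outputs.append(p)
    occ_path = out / "occurrences.csv"
    occ.to_csv(occ_path, index=False)
    outputs.append(occ_path)
    env_names_path = out / "env_names.json"
    env_names_path.write_text(json.dumps(world.env_names))
    outputs.append(env_names_path)
    return _entry(config, "simulate", [], outputs, n_records=len(occ))


def _load_world_rasters(config: RunConfig, out: Path):
    names = json.loads(_require(out, "env_names.json", "simulate").read_text())
    env_stack = {
        n: raster.read_ascii_grid(_require(out, f"env_{n}.asc", "simulate")) for n in names
    }
    class_grid = raster.read_ascii_grid(_require(out, "classes.asc", "simulate"), dtype=int)
    return env_stack, class_grid


def _stage_sites(config: RunConfig, out: Path) -> dict:
    occ_path = Path(config.occurrences_path) if config.occurrences_path else _require(
        out, "occurrences.csv", "simulate"
    )
    _, class_grid = _load_world_rasters(config, out)
    table, read_report = occurrences.read_occurrences(occ_path)
    table, boundary_report = occurrences.remove_boundary_records(
        table, class_grid, mode=config.boundary_mode
    )
    params = MCLParams(**config.mcl)
    coords = table[["decimalLatitude", "decimalLongitude"]].to_numpy()
    assignment = cluster_sites(coords, params)
    cm = occurrences.build_community_matrix(table, assignment)
    cm, filter_report = occurrences.filter_matrix(
        cm,
        min_sites_per_species=config.min_sites_per_species,
        min_obs_per_site=config.min_obs_per_site,
    )
    comm_path = out / "comm.csv"
    cm.to_csv(comm_path)
    sites_path = out / "sites.csv"
    cm.site_table().to_csv(sites_path, index=False)
    counts = dict(
        n_input_records=read_report["n_input"],
        n_parse_dropped=read_report["n_dropped"],
        n_boundary_removed=boundary_report["n_removed"],
        n_filter_dropped=filter_report["n_records_dropped"],
        n_records_retained=filter_report["n_records_retained"],
        n_sites=cm.n_sites,
        n_species=cm.n_species,
    )
    return _entry(config, "sites", [occ_path], [comm_path, sites_path], **counts)


def _stage_extract(config: RunConfig, out: Path) -> dict:
    env_stack, class_grid = _load_world_rasters(config, out)
    sites_path = _require(out, "sites.csv", "sites")
    sites = pd.read_csv(sites_path)
    env_table, report = envtable.build_env_table(
        sites, env_stack, class_grids={"ecoregion": class_grid}
    )
    env_path = out / "env_table.csv"
    env_table.to_csv(env_path, index=False)
    return _entry(
        config,
        "extract",
        [sites_path],
        [env_path],
        n_sites=report["n_sites"],
        n_excluded=report["n_excluded"],
    )


def _aligned_community(out: Path) -> tuple[occurrences.CommunityMatrix, pd.DataFrame]:
    """Community matrix restricted to the sites present in the env table."""
    comm = pd.read_csv(_require(out, "comm.csv", "sites"))
    env = pd.read_csv(_require(out, "env_table.csv", "extract"))
    comm = comm[comm["site"].isin(env["site"])].reset_index(drop=True)
    counts = comm.drop(columns="site").to_numpy()
    cm = occurrences.CommunityMatrix(
        counts=counts,
        site_ids=comm["site"].to_numpy(),
        species_ids=np.array(comm.columns[1:]),
        centroids=env[["lat", "lon"]].to_numpy(),
    )
    return cm, env


def _stage_dissim(config: RunConfig, out: Path) -> dict:
    cm, env = _aligned_community(out)
    seed = config.stage_seed("dissim")
    D = dsm.pairwise_dissimilarity(cm.counts, variant=config.dissimilarity_variant)
    G = dsm.geographic_distance(cm.centroids, haversine=config.haversine)
    ids = [str(s) for s in cm.site_ids]
    d_path = out / "dissimilarity.csv"
    pd.DataFrame(D, index=ids, columns=ids).to_csv(d_path)
    g_path = out / "geo_distance.csv"
    pd.DataFrame(G, index=ids, columns=ids).to_csv(g_path)
    contrasts = {}
    labels = env["ecoregion"].to_numpy()
    if np.unique(labels).size >= 2:
        res = dsm.class_contrast(D, labels, n_perm=config.mrm_n_perm, seed=seed)
        contrasts["ecoregion"] = {"r": res.r, "p": res.p, "n_perm": res.n_perm}
    c_path = out / "class_contrast.json"
    c_path.write_text(json.dumps(contrasts, indent=1, sort_keys=True))
    return _entry(
        config,
        "dissim",
        [out / "comm.csv", out / "env_table.csv"],
        [d_path, g_path, c_path],
        n_sites=cm.n_sites,
    )


def _env_var_split(env: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split continuous predictors into climate-like and vegetation-like sets."""
    skip = {"site", "lat", "lon", "ecoregion", "clime"}
    cont = [c for c in env.columns if c not in skip]
    veg = [c for c in cont if "cover" in c or c in ("tree", "herb", "bare")]
    clim = [c for c in cont if c not in veg]
    if not veg:  # fixture worlds name one cover-like layer
        veg = [c for c in cont if "tree" in c] or cont[-1:]
        clim = [c for c in cont if c not in veg]
    return clim, veg


def _stage_mrm(config: RunConfig, out: Path) -> dict:
    d_path = _require(out, "dissimilarity.csv", "dissim")
    g_path = _require(out, "geo_distance.csv", "dissim")
    env = pd.read_csv(_require(out, "env_table.csv", "extract"))
    D = pd.read_csv(d_path, index_col=0).to_numpy()
    G = pd.read_csv(g_path, index_col=0).to_numpy()
    clim, veg = _env_var_split(env)
    seed = config.stage_seed("mrm")
    table = mrm.model_comparison(
        D,
        G,
        climate=mrm.env_distance_matrices(env, clim),
        vegetation=mrm.env_distance_matrices(env, veg),
        n_perm=config.mrm_n_perm,
        seed=seed,
    )
    t_path = out / "mrm_table.csv"
    table.to_csv(t_path, index=False)
    return _entry(config, "mrm", [d_path, g_path], [t_path], n_models=len(table))


def _stage_gdm(config: RunConfig, out: Path) -> dict:
    d_path = _require(out, "dissimilarity.csv", "dissim")
    env = pd.read_csv(_require(out, "env_table.csv", "extract"))
    cm, _ = _aligned_community(out)
    D = pd.read_csv(d_path, index_col=0).to_numpy()
    predictors = ["lat", "lon"] + _env_var_split(env)[0] + _env_var_split(env)[1]
    pairs = gdm.build_site_pairs(D, env, cm.richness(), predictors=predictors)
    seed = config.stage_seed("gdm")
    model = gdm.fit_gdm(pairs, n_splines=config.gdm_n_splines)
    summary = gdm.predictor_significance(
        pairs,
        n_splines=config.gdm_n_splines,
        n_perm=config.gdm_n_perm,
        seed=seed,
        alpha=config.gdm_alpha,
        model=model,
    )
    m_path = out / "gdm_model.txt"
    model.save(m_path)
    s_path = out / "gdm_significance.csv"
    summary.table.to_csv(s_path, index=False)
    pairs_path = out / "site_pairs.csv"
    pairs.to_frame().to_csv(pairs_path, index=False)
    plot_path = out / "gdm_splines.png"
    _plot_splines(model, plot_path)
    return _entry(
        config,
        "gdm",
        [d_path, out / "env_table.csv"],
        [m_path, s_path, pairs_path],
        n_pairs=pairs.n_pairs,
        pct_deviance_explained=model.pct_deviance_explained,
    )


def _plot_splines(model: gdm.GDMModel, path: Path) -> None:
    """Partial-ecological-distance curves per predictor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = model.predictor_names
    ncol = min(4, len(names))
    nrow = -(-len(names) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, name in zip(axes.ravel(), names):
        knots = model.basis.knots[name]
        x = np.linspace(knots[0], knots[-1], 200)
        y = model.basis.evaluate(name, x) @ model.coefficients[name]
        ax.plot(x, y)
        ax.set_title(name, fontsize=9)
        ax.set_ylabel("partial ecological distance", fontsize=7)
    for ax in axes.ravel()[len(names) :]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _stage_map(config: RunConfig, out: Path) -> dict:
    m_path = _require(out, "gdm_model.txt", "gdm")
    s_path = _require(out, "gdm_significance.csv", "gdm")
    model = gdm.GDMModel.load(m_path)
    summary = pd.read_csv(s_path)
    env_stack, _ = _load_world_rasters(config, out)
    ref = next(iter(env_stack.values()))
    lat_grid, lon_grid = raster.latlon_grids(ref)
    stack = {"lat": lat_grid, "lon": lon_grid, **env_stack}
    kept = summary.loc[summary["keep"], "predictor"].tolist()
    if len(kept) < 1:  # fall back to all modeled predictors rather than no map
        kept = model.predictor_names
    transformed = gdm.transform_env(model, stack, predictors=kept)
    rgb, valid, transform = gdm.beta_map(transformed)
    tif_path = out / "beta_map.tif"
    raster.write_geotiff(rgb, tif_path, transform=transform)
    png_path = out / "beta_map.png"
    from PIL import Image

    Image.fromarray(rgb).save(png_path)
    return _entry(
        config,
        "map",
        [m_path, s_path],
        [tif_path, png_path],
        n_layers=len(transformed),
        n_valid_pixels=int(valid.sum()),
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sites": _stage_sites,
    "extract": _stage_extract,
    "dissim": _stage_dissim,
    "mrm": _stage_mrm,
    "gdm": _stage_gdm,
    "map": _stage_map,
}


def run_stage(stage: str, config: RunConfig) -> dict:
    """Run one pipeline stage; returns (and appends) its manifest entry."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entry = _STAGE_FUNCS[stage](config, out)
    _manifest_append(out, entry)
    return entry


def run_all(config: RunConfig) -> list[dict]:
    """Run every stage in order."""
    return [run_stage(stage, config) for stage in STAGES]
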