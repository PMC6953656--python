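"""Synthetic worlds with known community-turnover ground truth.

Stands in for the real inputs of a continental occurrence-mining study:
smooth environmental surfaces (bioclim-like and vegetation-cover-like),
a categorical region map (ecoregion/clime analog), a species pool with
Gaussian niches and hard circular dispersal ranges, spatially uneven
sampling effort, and GBIF-style occurrence records drawn from the
resulting intensity surface.

Every generator is a pure function of its configuration and seed, so
regenerating with the same seed is bit-identical.  The expected
(noise-free) per-pixel abundance field gives exact ground-truth
dissimilarities for parameter-recovery experiments.

The abundance model is a Gaussian niche times a hard spatial range disc:

    lambda_s(pixel) = I_s * exp(-sum_v (e_v - o_sv)^2 / (2 b_sv^2)) * 1[|p - c_s| <= r_s]

with intensity I_s, niche optimum o_s, breadth b_s, range center c_s and
radius r_s (degrees).  This is the simplest generative model realizing
both environmental filtering and dispersal limitation as drivers of
compositional turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.ndimage import gaussian_filter

from .dissimilarity import horn_morisita
from .raster import RasterGrid

__all__ = [
    "SyntheticWorld",
    "SpeciesPool",
    "generate_world",
    "generate_species_pool",
    "two_patch_effort",
    "expected_abundance",
    "sample_occurrences",
    "true_pair_dissimilarity",
    "fixture_world",
    "FIXTURE_CONFIG",
]


@dataclass
class SyntheticWorld:
    """A generated study region: environmental stack plus region classes."""

    extent: tuple[float, float, float, float]  # west, south, east, north
    grid_shape: tuple[int, int]
    env_stack: dict[str, RasterGrid]
    class_grid: RasterGrid
    seed: int

    @property
    def env_names(self) -> list[str]:
        return list(self.env_stack)

    def env_array(self) -> np.ndarray:
        """(n_vars, rows, cols) stack of the continuous surfaces."""
        return np.stack([g.values for g in self.env_stack.values()])

    def reference_grid(self) -> RasterGrid:
        return next(iter(self.env_stack.values()))


@dataclass
class SpeciesPool:
    """Niche and dispersal parameters for every species, aligned to the world."""

    env_names: list[str]
    niche_optimum: np.ndarray  # (n_species, n_vars)
    niche_breadth: np.ndarray  # (n_species, n_vars), strictly positive
    max_intensity: np.ndarray  # (n_species,)
    range_center: np.ndarray  # (n_species, 2) as (lat, lon)
    range_radius: np.ndarray  # (n_species,) degrees

    def __post_init__(self) -> None:
        if (self.niche_breadth <= 0).any():
            raise ValueError("niche breadths must be strictly positive")
        if self.niche_optimum.shape != self.niche_breadth.shape:
            raise ValueError("optimum/breadth shape mismatch")
        if self.niche_optimum.shape[1] != len(self.env_names):
            raise ValueError("one niche entry per environmental variable required")

    @property
    def n_species(self) -> int:
        return self.niche_optimum.shape[0]

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i:04d}" for i in range(self.n_species)]


def _env_var_names(n: int) -> list[str]:
    base = ["temp_like", "precip_like", "treecover_like"]
    names = base[:n]
    names += [f"env{i + 1:02d}" for i in range(len(names), n)]
    return names


def generate_world(
    extent=(-10.0, 30.0, 14.0, 54.0),
    grid_shape=(24, 24),
    n_env_vars: int = 5,
    n_classes: int = 3,
    seed: int = 0,
    gradient_only: bool = False,
    smoothness: float = 2.5,
    gradient_weight: float = 0.6,
) -> SyntheticWorld:
    """Generate smooth environmental surfaces and a contiguous class map.

    Each continuous surface is low-pass-filtered Gaussian noise blended
    with a monotone latitudinal gradient, min-max scaled to [0, 100].
    With ``gradient_only`` the surface is the pure gradient (strictly
    monotone in the row index, constant along rows).  The class map
    partitions the grid by k-means over spatial position and smoothed
    environment, giving spatially coherent regions labelled 0..k-1.
    """
    west, south, east, north = extent
    if not (east > west and north > south):
        raise ValueError("degenerate extent: zero or negative width/height")
    rows, cols = grid_shape
    if rows < 8 or cols < 8:
        raise ValueError("grid_shape must be at least 8 x 8")
    if n_env_vars < 1:
        raise ValueError("n_env_vars must be >= 1")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    transform = ((east - west) / cols, 0.0, west, 0.0, -(north - south) / rows, north)

    env_stack: dict[str, RasterGrid] = {}
    # strictly increasing from north row to south row (warm toward equator)
    gradient = np.linspace(0.0, 1.0, rows)[:, None] * np.ones((1, cols))
    for name in _env_var_names(n_env_vars):
        if gradient_only:
            field = gradient.copy()
        else:
            noise = gaussian_filter(rng.standard_normal((rows, cols)), sigma=smoothness)
            noise = (noise - noise.min()) / (noise.max() - noise.min() + 1e-12)
            field = gradient_weight * gradient + (1.0 - gradient_weight) * noise
        field = 100.0 * (field - field.min()) / (field.max() - field.min() + 1e-12)
        env_stack[name] = RasterGrid(field, transform)

    if n_classes == 1:
        labels = np.zeros((rows, cols), dtype=int)
    else:
        rr, cc = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij")
        feats = [rr.ravel(), cc.ravel()]
        for g in env_stack.values():
            sm = gaussian_filter(g.values, sigma=max(smoothness, 2.0))
            feats.append(0.5 * (sm.ravel() - sm.min()) / (np.ptp(sm) + 1e-12))
        X = np.column_stack(feats)
        _, lab = kmeans2(X, n_classes, minit="++", seed=rng, missing="warn")
        # relabel deterministically by first occurrence, contiguous from 0
        _, lab = np.unique(lab, return_inverse=True)
        order = {}
        for v in lab:
            if v not in order:
                order[v] = len(order)
        labels = np.array([order[v] for v in lab]).reshape(rows, cols)
    class_grid = RasterGrid(labels.astype(int), transform, nodata=-1)
    return SyntheticWorld(extent, (rows, cols), env_stack, class_grid, seed)


def generate_species_pool(
    world: SyntheticWorld,
    n_species: int = 40,
    seed: int = 0,
    breadth_frac=(0.15, 0.6),
    radius_frac=(0.35, 0.9),
    intensity_sigma: float = 0.5,
) -> SpeciesPool:
    """Draw a species pool with niches inside the observed env ranges.

    Breadths are uniform fractions of each variable's observed range and
    range radii uniform fractions of the extent half-diagonal, so every
    species has support somewhere on the map; intensities are lognormal.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    env = world.env_array()
    lo = env.min(axis=(1, 2))
    hi = env.max(axis=(1, 2))
    span = np.maximum(hi - lo, 1e-9)
    nv = env.shape[0]
    optimum = rng.uniform(lo, hi, size=(n_species, nv))
    breadth = rng.uniform(*breadth_frac, size=(n_species, nv)) * span
    intensity = rng.lognormal(mean=0.0, sigma=intensity_sigma, size=n_species)
    west, south, east, north = world.extent
    centers = np.column_stack(
        [rng.uniform(south, north, n_species), rng.uniform(west, east, n_species)]
    )
    half_diag = 0.5 * float(np.hypot(east - west, north - south))
    radius = rng.uniform(*radius_frac, size=n_species) * half_diag
    return SpeciesPool(world.env_names, optimum, breadth, intensity, centers, radius)


def two_patch_effort(world: SyntheticWorld, ratio: float = 10.0) -> RasterGrid:
    """Default sampling-effort surface: a high/low longitudinal split.

    The western half of the map is sampled ``ratio`` times more
    intensively than the eastern half, emulating the strong regional
    bias of ad hoc occurrence databases.
    """
    rows, cols = world.grid_shape
    eff = np.ones((rows, cols))
    eff[:, : cols // 2] = ratio
    return RasterGrid(eff, world.reference_grid().transform)


def expected_abundance(world: SyntheticWorld, pool: SpeciesPool) -> np.ndarray:
    """(n_species, rows, cols) noise-free expected abundance field."""
    env = world.env_array()  # (V, R, C)
    grid = world.reference_grid()
    rows, cols = world.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    lon, lat = grid.cell_center(rr, cc)
    d2 = (env[None] - pool.niche_optimum[:, :, None, None]) ** 2
    expo = -0.5 * (d2 / pool.niche_breadth[:, :, None, None] ** 2).sum(axis=1)
    lam = pool.max_intensity[:, None, None] * np.exp(expo)
    dist = np.hypot(
        lat[None] - pool.range_center[:, 0, None, None],
        lon[None] - pool.range_center[:, 1, None, None],
    )
    lam = lam * (dist <= pool.range_radius[:, None, None])
    return lam


def sample_occurrences(
    world: SyntheticWorld,
    pool: SpeciesPool,
    effort: RasterGrid,
    n_records: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw GBIF-like records from the effort-weighted intensity field.

    Pixels are drawn from an effort-weighted multinomial over total
    expected abundance, species within a pixel from its composition, and
    coordinates jittered uniformly within the pixel so that records are
    not grid-aligned.  Columns follow Darwin Core naming.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if effort.shape != world.grid_shape:
        raise ValueError("effort grid must match world shape")
    eff = np.asarray(effort.values, dtype=float)
    if (eff < 0).any() or not np.isfinite(eff).all():
        raise ValueError("effort must be finite and non-negative")
    lam = expected_abundance(world, pool)  # (S, R, C)
    pix_weight = (eff[None] * lam).sum(axis=0)
    total = pix_weight.sum()
    if total <= 0:
        raise ValueError("effort is zero everywhere any species has support")
    rng = np.random.default_rng(seed)
    rows, cols = world.grid_shape
    flat_p = (pix_weight / total).ravel()
    pix = rng.choice(rows * cols, size=n_records, p=flat_p)
    species = np.empty(n_records, dtype=int)
    # draw species per unique pixel to keep the multinomials vectorized
    for px in np.unique(pix):
        sel = pix == px
        r, c = divmod(int(px), cols)
        comp = lam[:, r, c]
        species[sel] = rng.choice(pool.n_species, size=int(sel.sum()), p=comp / comp.sum())
    r, c = np.divmod(pix, cols)
    grid = world.reference_grid()
    a, _, cx, _, e, f = grid.transform
    lon = cx + a * (c + rng.uniform(0, 1, n_records))
    lat = f + e * (r + rng.uniform(0, 1, n_records))
    ids = np.array(pool.species_ids)
    return pd.DataFrame(
        {"species": ids[species], "decimalLatitude": lat, "decimalLongitude": lon}
    )


def true_pair_dissimilarity(
    world: SyntheticWorld, pool: SpeciesPool, cell_a: tuple[int, int], cell_b: tuple[int, int]
) -> float:
    """Ground-truth Horn-Morisita between the expected communities of two cells."""
    rows, cols = world.grid_shape
    for r, c in (cell_a, cell_b):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"cell ({r}, {c}) outside the world grid")
    lam = expected_abundance(world, pool)
    x = lam[:, cell_a[0], cell_a[1]]
    y = lam[:, cell_b[0], cell_b[1]]
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("dissimilarity undefined: cell with all-zero expected abundance")
    return horn_morisita(x, y)


#: Study conditions for the packaged small world used throughout the tests.
FIXTURE_CONFIG = dict(
    extent=(-10.0, 30.0, 14.0, 54.0),
    grid_shape=(24, 24),
    n_env_vars=5,
    n_classes=3,
    n_species=40,
    n_records=20_000,
    effort_ratio=10.0,
)


def fixture_world(seed: int = 0, n_records: int | None = None):
    """The packaged 24x24 fixture world: (world, pool, effort, occurrences)."""
    cfg = FIXTURE_CONFIG
    world = generate_world(
        extent=cfg["extent"],
        grid_shape=cfg["grid_shape"],
        n_env_vars=cfg["n_env_vars"],
        n_classes=cfg["n_classes"],
        seed=seed,
    )
    pool = generate_species_pool(world, n_species=cfg["n_species"], seed=seed + 1)
    effort = two_patch_effort(world, ratio=cfg["effort_ratio"])
    occ = sample_occurrences(
        world, pool, effort, n_records or cfg["n_records"], seed=seed + 2
    )
    return world, pool, effort, occ
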