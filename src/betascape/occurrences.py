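"""Occurrence-table ingestion, boundary cleaning and community matrices.

The raw input is a Darwin-Core-style CSV of georeferenced species
records.  The processing chain is:

1. parse and range-check coordinates (dropped rows are counted, never
   silently discarded);
2. remove records in 0.1-degree cells that straddle a region-class
   boundary, where mixed-provenance communities would blur class
   contrasts;
3. group records into geographic sample sites (see :mod:`betascape.mcl`);
4. tally the site x species abundance matrix;
5. iterate the sparsity filters (species seen at too few sites, sites
   with too few records) to a fixed point.

Every stage reports how many records or rows it removed so the pipeline
can assert conservation: records_in = retained + dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid, classify_points

__all__ = [
    "read_occurrences",
    "remove_boundary_records",
    "build_community_matrix",
    "filter_matrix",
    "CommunityMatrix",
]

# Darwin Core and common shorthand column aliases, checked in order.
DEFAULT_ALIASES = {
    "species": ["species", "scientificName", "speciesKey", "taxon"],
    "decimalLatitude": ["decimalLatitude", "latitude", "lat"],
    "decimalLongitude": ["decimalLongitude", "longitude", "lon", "long"],
}


def read_occurrences(path, aliases: dict | None = None):
    """Read an occurrence CSV, dropping and counting malformed rows.

    Returns ``(table, report)`` where the table has canonical columns
    ``species``, ``decimalLatitude``, ``decimalLongitude`` and the report
    counts rows dropped for unparseable or out-of-range coordinates or
    empty species identifiers.
    """
    aliases = aliases or DEFAULT_ALIASES
    df = pd.read_csv(path)
    cols = {}
    for canon, names in aliases.items():
        for name in names:
            if name in df.columns:
                cols[canon] = name
                break
        else:
            raise ValueError(f"missing required column {canon!r} (accepted: {names})")
    out = df[[cols["species"], cols["decimalLatitude"], cols["decimalLongitude"]]].copy()
    out.columns = ["species", "decimalLatitude", "decimalLongitude"]
    n_in = len(out)
    out["decimalLatitude"] = pd.to_numeric(out["decimalLatitude"], errors="coerce")
    out["decimalLongitude"] = pd.to_numeric(out["decimalLongitude"], errors="coerce")
    out["species"] = out["species"].astype(str).str.strip()
    ok = (
        out["decimalLatitude"].between(-90, 90)
        & out["decimalLongitude"].between(-180, 180)
        & out["decimalLatitude"].notna()
        & out["decimalLongitude"].notna()
        & (out["species"] != "")
        & (out["species"].str.lower() != "nan")
    )
    out = out[ok].reset_index(drop=True)
    report = {"n_input": n_in, "n_retained": len(out), "n_dropped": int(n_in - len(out))}
    return out, report


def remove_boundary_records(
    table: pd.DataFrame, class_grid: RasterGrid, mode: str = "cell_corners"
):
    """Remove records from 0.1-degree cells lying on region-class boundaries.

    Records are binned by their coordinates rounded to one decimal place
    (cells of roughly 5 km half-width).  Under the default
    ``cell_corners`` rule, a bin is a boundary bin when the class grid
    disagrees across the bin's four corners and center — a
    record-independent criterion.  The alternative ``record_pixels`` rule
    instead marks a bin when the classes under its own records differ.
    All records in boundary bins are removed.

    Returns ``(table, report)`` with the count of removed records.
    """
    if mode not in ("cell_corners", "record_pixels"):
        raise ValueError(f"unknown boundary mode {mode!r}")
    if table.empty:
        return table.copy(), {"n_input": 0, "n_removed": 0, "n_retained": 0, "n_boundary_bins": 0}
    lats = table["decimalLatitude"].to_numpy(dtype=float)
    lons = table["decimalLongitude"].to_numpy(dtype=float)
    inside = class_grid.contains(lons, lats)
    if not inside.all():
        bad = table.index[~inside].tolist()
        raise ValueError(f"records outside class grid extent: rows {bad[:10]}")
    bin_lat = np.round(lats, 1)
    bin_lon = np.round(lons, 1)
    bins = pd.DataFrame({"blat": bin_lat, "blon": bin_lon})
    uniq = bins.drop_duplicates().reset_index(drop=True)

    west, south, east, north = class_grid.extent
    eps = 1e-9

    def clamp(lon, lat):
        return (
            np.clip(lon, west, east - eps),
            np.clip(lat, south + eps, north),
        )

    boundary = np.zeros(len(uniq), dtype=bool)
    if mode == "cell_corners":
        offsets = [(0.0, 0.0), (-0.05, -0.05), (-0.05, 0.05), (0.05, -0.05), (0.05, 0.05)]
        for k, (dlat, dlon) in enumerate(offsets):
            lon_s, lat_s = clamp(uniq["blon"].to_numpy() + dlon, uniq["blat"].to_numpy() + dlat)
            res = classify_points(class_grid, lon_s, lat_s)
            labels = res.values.astype(int)
            if k == 0:
                ref = labels
            else:
                boundary |= labels != ref
    else:
        res = classify_points(class_grid, lons, lats)
        labels = res.values.astype(int)
        key = pd.MultiIndex.from_arrays([bin_lat, bin_lon])
        n_classes = pd.Series(labels, index=key).groupby(level=[0, 1]).nunique()
        mixed = set(n_classes[n_classes > 1].index)
        boundary = np.array(
            [(la, lo) in mixed for la, lo in zip(uniq["blat"], uniq["blon"])]
        )

    boundary_bins = set(
        (la, lo) for la, lo, b in zip(uniq["blat"], uniq["blon"], boundary) if b
    )
    is_boundary = np.array([(la, lo) in boundary_bins for la, lo in zip(bin_lat, bin_lon)])
    kept = table[~is_boundary].reset_index(drop=True)
    report = {
        "n_input": len(table),
        "n_removed": int(is_boundary.sum()),
        "n_retained": len(kept),
        "n_boundary_bins": len(boundary_bins),
    }
    return kept, report


@dataclass
class CommunityMatrix:
    """Site x species abundance counts with site geography attached."""

    counts: np.ndarray  # (n_sites, n_species) non-negative ints
    site_ids: np.ndarray  # (n_sites,)
    species_ids: np.ndarray  # (n_species,)
    centroids: np.ndarray  # (n_sites, 2) mean (lat, lon)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def richness(self) -> np.ndarray:
        """Species richness (count of nonzero species) per site."""
        return (self.counts > 0).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species_ids)
        df.insert(0, "site", self.site_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_ids,
                "lat": self.centroids[:, 0],
                "lon": self.centroids[:, 1],
                "n_records": self.counts.sum(axis=1),
            }
        )


def build_community_matrix(table: pd.DataFrame, assignment) -> CommunityMatrix:
    """Tally records into the site x species abundance matrix.

    The total count equals the number of records by construction.
    """
    if len(table) != assignment.site_id.shape[0]:
        raise ValueError("assignment must cover every record")
    species = pd.Categorical(table["species"])
    sp_ids = np.asarray(species.categories)
    n_sites = assignment.n_sites
    counts = np.zeros((n_sites, len(sp_ids)), dtype=int)
    np.add.at(counts, (assignment.site_id, species.codes), 1)
    return CommunityMatrix(
        counts=counts,
        site_ids=np.arange(n_sites),
        species_ids=sp_ids,
        centroids=assignment.centroids.copy(),
    )


def filter_matrix(
    cm: CommunityMatrix, min_sites_per_species: int = 30, min_obs_per_site: int = 300
):
    """Iterate the sparsity filters to a fixed point.

    Each pass removes species present at fewer than
    ``min_sites_per_species`` sites, then sites with total abundance
    below ``min_obs_per_site``; removing sites can push species back
    under threshold, so passes repeat until nothing changes.  Returns
    ``(filtered, report)`` where the report lists removals per pass.

    Raises if the fixed point is empty.
    """
    if min_sites_per_species < 1 or min_obs_per_site < 1:
        raise ValueError("thresholds must be >= 1")
    counts = cm.counts.copy()
    site_idx = np.arange(cm.n_sites)
    sp_idx = np.arange(cm.n_species)
    passes = []
    while True:
        sp_keep = (counts > 0).sum(axis=0) >= min_sites_per_species
        counts = counts[:, sp_keep]
        sp_idx = sp_idx[sp_keep]
        site_keep = counts.sum(axis=1) >= min_obs_per_site
        counts = counts[site_keep]
        site_idx = site_idx[site_keep]
        removed = {
            "species_removed": int((~sp_keep).sum()),
            "sites_removed": int((~site_keep).sum()),
        }
        passes.append(removed)
        if removed["species_removed"] == 0 and removed["sites_removed"] == 0:
            break
        if counts.size == 0:
            raise ValueError("no data survive filters")
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError("no data survive filters")
    filtered = CommunityMatrix(
        counts=counts,
        site_ids=cm.site_ids[site_idx],
        species_ids=cm.species_ids[sp_idx],
        centroids=cm.centroids[site_idx],
    )
    report = {
        "passes": passes,
        "n_sites": filtered.n_sites,
        "n_species": filtered.n_species,
        "n_records_retained": int(counts.sum()),
        "n_records_dropped": int(cm.counts.sum() - counts.sum()),
    }
    return filtered, report
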