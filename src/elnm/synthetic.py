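"""Synthetic New-Guinea-like world with planted, recoverable niches.

Generates everything the pipeline consumes — monthly climate, a DEM with an
island coastline, language-territory polygons, villages — together with the
ground truth needed for recovery tests: each group's planted environmental
stratum and the planted pattern (ELP) partition.

The world is built so the major axes of real tropical-island environments are
present: a mountainous interior with elevation-driven temperature lapse (so
altitude and temperature covary strongly, the dominant axis of the
environment), a weak latitudinal temperature gradient, mild tropical
seasonality, a stepped hypsometry of plateaus joined by scarps, and a
windward/leeward rain-shadow contrast across the coastal plain.  Language
groups occupy environmental strata defined as intervals of annual mean
temperature (elevation belts) and annual precipitation: several "highland"
groups share one cool stratum (a planted multi-group pattern), and coastal
strata hold singleton groups, mimicking the observed structure of highland
diversity versus confined coastal niches.  Villages are sampled uniformly in
geographic space within each territory, so occurrence sampling carries the
same spatial bias as real gazetteers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy, unary_union
from shapely.geometry import box

from .bioclim import add_bioclim
from .elp import ELPRecord
from .models import SuitabilityMap
from .occurrences import LanguageGroup
from .raster import EnvStack, Grid, Layer
from .terrain import add_terrain

#: (stratum name, number of groups, family) — the planted pattern structure:
#: one 3-group highland pattern, one 2-group mid-elevation pattern, and three
#: singleton lowland/coastal patterns split by precipitation.
DEFAULT_STRATA = (
    ("highland", 3, "TNG"),
    ("mid_elevation", 2, "TNG"),
    ("lowland_warm", 1, "TNG"),
    ("lowland_wet", 1, "Austronesian"),
    ("lowland_dry", 1, "Austronesian"),
)


@dataclass
class SyntheticWorldConfig:
    n_rows: int = 200
    n_cols: int = 200
    seed: int = 0
    origin_lon: float = 130.0
    origin_lat: float = 0.0
    cell_size: float = 0.05
    strata: tuple = DEFAULT_STRATA
    villages_per_group: tuple[int, int] = (60, 120)
    smoothness: float = 18.0          # length-scale of coastline/DEM noise, cells
    climate_noise_scale: float = 5.0  # length-scale of climate noise, cells
    noise_sd: float = 0.1             # deg C sd of temperature noise
    lapse_c_per_km: float = 6.5
    sea_level: float = 0.0


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    stack: EnvStack
    groups: list[LanguageGroup]
    villages: dict[str, np.ndarray]            # group_id -> (n, 2) lon/lat
    true_niches: dict[str, SuitabilityMap]     # planted binary envelope maps
    planted_elps: dict[str, str]               # group_id -> stratum name
    strata_bounds: dict[str, dict]             # stratum -> variable intervals

    @property
    def families(self) -> dict[str, str]:
        return {g.group_id: g.family for g in self.groups}

    def planted_partition(self, group_ids: list[str] | None = None) -> np.ndarray:
        ids = group_ids or [g.group_id for g in self.groups]
        names = sorted(set(self.planted_elps.values()))
        return np.array([names.index(self.planted_elps[g]) for g in ids])


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-convolved white noise)."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_climate_dem(config: SyntheticWorldConfig
                         ) -> tuple[list[Layer], list[Layer], list[Layer], Layer]:
    """Monthly tmin/tmax/prec (deg C, mm) and a DEM (m) on the config grid.

    The island is an elongated massif with a stepped hypsometry; cells at or
    below sea level are nodata (sea).  Temperature follows a lapse of
    ``lapse_c_per_km`` off the smooth elevation plus a weak latitudinal
    gradient and a small seasonal cycle; precipitation is positive, mildly
    seasonal, and split into windward (wet) and leeward (dry) coastal
    regimes by the central massif.
    """
    g = Grid(config.n_rows, config.n_cols, config.origin_lon, config.origin_lat,
             config.cell_size)
    rng = np.random.default_rng(config.seed)
    rr, cc = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols),
                         indexing="ij")
    y = rr / (config.n_rows - 1)          # 0 north -> 1 south
    x = cc / (config.n_cols - 1)

    # island: a broad elongated massif, highest mid-island, negative near the
    # borders.  The hypsometry is stepped — coastal plain, foothill and
    # montane plateaus, and a highland plateau joined by short steep scarps —
    # the intermontane-plateau structure characteristic of large tropical
    # islands.  Discrete elevation belts give the island discrete eco-zones
    # with narrow transition slopes between them.
    ridge = 3400.0 * np.exp(-(((y - 0.5) / 0.16) ** 2) - (((x - 0.5) / 0.42) ** 2))
    base = 900.0 * np.exp(-(((y - 0.5) / 0.30) ** 2) - (((x - 0.5) / 0.55) ** 2))
    latent = ridge + base - 250.0 + 120.0 * _smooth_field(rng, g.shape,
                                                          config.smoothness)

    def _scarp(z):
        return 1.0 / (1.0 + np.exp(-z))

    sea = latent <= config.sea_level
    # scarp positions at fixed quantiles of the land hypsometry, so the
    # plateau belts occupy comparable areas whatever the noise realization;
    # equal 650 m steps keep adjacent belts ~4 deg C apart
    land_latent = latent[~sea]
    t1, t2, t3, t4 = (float(np.quantile(land_latent, q))
                      for q in (0.30, 0.45, 0.60, 0.75))
    dem_smooth = (60.0
                  + 650.0 * _scarp((latent - t1) / 45.0)
                  + 650.0 * _scarp((latent - t2) / 45.0)
                  + 650.0 * _scarp((latent - t3) / 45.0)
                  + 650.0 * _scarp((latent - t4) / 45.0))
    # the DEM additionally carries fine-scale ruggedness, which mixes local
    # slope directions so no territory sits on one coherent flank
    ruggedness = 30.0 * _smooth_field(rng, g.shape, 2.0)
    dem = dem_smooth + ruggedness
    dem_layer = Layer(g, np.where(sea, 0.0, dem), sea, "DEM")

    # annual-mean temperature: lapse off the smooth elevation plus a weak
    # latitudinal trend.  Climate noise uses a short length-scale: local
    # texture every territory samples, rather than regional offsets that
    # would make territories of one stratum environmentally distinguishable.
    cs = config.climate_noise_scale
    t_base = (27.5 - 1.2 * y
              - config.lapse_c_per_km * np.clip(dem_smooth, 0, None) / 1000.0)
    t_noise = config.noise_sd * _smooth_field(rng, g.shape, cs)
    diurnal = 7.0 + 0.25 * _smooth_field(rng, g.shape, cs)
    diurnal = np.clip(diurnal, 4.0, 11.0)

    # precipitation: a windward/leeward regime split — the massif shields the
    # southern lowlands, so the coastal plain is wet north of the divide and
    # dry south of it with a sharp rain-shadow transition, while the uplands
    # keep only a mild latitudinal gradient.  Gradients run along latitude,
    # so territories split along longitude see exchangeable environments.
    lowlandness = np.exp(-np.clip(dem_smooth, 0, None) / 300.0)
    rain_shadow = _scarp((y - 0.5) / 0.08)
    p_base = (300.0 - 40.0 * y * (1.0 - lowlandness)
              - 170.0 * lowlandness * rain_shadow
              + 4.0 * _smooth_field(rng, g.shape, cs))
    p_season_amp = 70.0 + 3.0 * _smooth_field(rng, g.shape, cs)

    months = np.arange(12)
    tmin, tmax, prec = [], [], []
    for m in months:
        seas_t = 1.3 * np.cos(2 * np.pi * (m - 0.5) / 12.0)
        tm = t_base + t_noise + seas_t
        tmin.append(Layer(g, np.where(sea, 0.0, tm - diurnal / 2), sea.copy(),
                          f"tmin{m + 1:02d}"))
        tmax.append(Layer(g, np.where(sea, 0.0, tm + diurnal / 2), sea.copy(),
                          f"tmax{m + 1:02d}"))
        seas_p = np.cos(2 * np.pi * (m - 1) / 12.0 + np.pi * y)
        pv = np.clip(p_base + p_season_amp * seas_p, 0.0, None)
        prec.append(Layer(g, np.where(sea, 0.0, pv), sea.copy(), f"prec{m + 1:02d}"))
    return tmin, tmax, prec, dem_layer


def assemble_stack(tmin: list[Layer], tmax: list[Layer], prec: list[Layer],
                   dem: Layer) -> EnvStack:
    """Full 26-variable stack: 19 bioclim + DEM and 6 terrain derivatives."""
    stack = EnvStack(dem.grid)
    stack.add_monthly("tmin", tmin)
    stack.add_monthly("tmax", tmax)
    stack.add_monthly("prec", prec)
    add_bioclim(stack)
    add_terrain(stack, dem)
    return stack


def _stratum_masks(stack: EnvStack, strata) -> tuple[dict[str, np.ndarray], dict[str, dict]]:
    """Land masks and variable intervals for each stratum.

    Strata are separated bands of annual mean temperature (elevation belts),
    with the warmest coastal belt split into wet and dry halves by annual
    precipitation; the gaps between intervals keep the planted niches
    environmentally disjoint."""
    valid = ~stack.shared_mask
    bio1 = stack["bio1"].values
    bio12 = stack["bio12"].values
    warm = 25.3
    p_warm = bio12[valid & (bio1 >= warm)]
    if p_warm.size == 0:
        raise RuntimeError("no warm coastal belt in this world")
    # coastal precipitation is bimodal (windward wet vs leeward dry regime);
    # place the wet/dry cuts in the gap between the two modes
    lo_mode = float(np.quantile(p_warm, 0.25))
    hi_mode = float(np.quantile(p_warm, 0.75))
    center = 0.5 * (lo_mode + hi_mode)
    margin = 0.12 * (hi_mode - lo_mode)
    wet_cut = center + margin
    dry_cut = center - margin
    bounds = {
        "highland": {"bio1": (12.9, 14.7)},
        "mid_elevation": {"bio1": (17.1, 18.9)},
        "lowland_warm": {"bio1": (21.4, 23.2)},
        "lowland_wet": {"bio1": (warm, np.inf), "bio12": (wet_cut, np.inf)},
        "lowland_dry": {"bio1": (warm, np.inf), "bio12": (-np.inf, dry_cut)},
    }
    masks = {}
    for name, _, _ in strata:
        iv = bounds[name]
        m = valid.copy()
        for var, (lo, hi) in iv.items():
            vals = stack[var].values
            m &= (vals >= lo) & (vals <= hi)
        if not m.any():
            raise RuntimeError(f"stratum {name!r} is empty in this world")
        masks[name] = m
    return masks, {name: bounds[name] for name, _, _ in strata}


def _cells_to_polygon(cells: np.ndarray, grid: Grid):
    """Union of cell squares.  The polygon covers the stratum cells exactly,
    margins included, so villages sample the full environmental breadth of
    the planted niche."""
    rows, cols = np.nonzero(cells)
    boxes = []
    cs = grid.cell_size
    for r, c in zip(rows, cols):
        lon0 = grid.origin_lon + c * cs
        lat1 = grid.origin_lat - r * cs
        boxes.append(box(lon0, lat1 - cs, lon0 + cs, lat1))
    poly = unary_union(boxes)
    return poly.buffer(0)


def plant_language_world(stack: EnvStack, config: SyntheticWorldConfig
                         ) -> SyntheticWorld:
    """Carve polygons inside each stratum's largest component, drop villages,
    and record the planted (true) niches."""
    rng = np.random.default_rng(config.seed + 1)
    masks, bounds = _stratum_masks(stack, config.strata)

    groups: list[LanguageGroup] = []
    villages: dict[str, np.ndarray] = {}
    true_niches: dict[str, SuitabilityMap] = {}
    planted: dict[str, str] = {}
    gid_counter = 0
    block = 6  # stripe width, cells; narrower than the climate noise scale
    for name, n_groups, family in config.strata:
        m = masks[name]
        if not m.any():
            raise RuntimeError(f"stratum {name!r} is empty; world too small")
        # Multi-group strata are split into interleaved longitude stripes:
        # every territory samples the stratum's full environmental breadth,
        # so groups sharing a stratum are environmentally exchangeable (the
        # condition that makes them one planted pattern).
        cols_present = np.nonzero(m.any(axis=0))[0]
        block_of_col = np.zeros(m.shape[1], dtype=int)
        block_of_col[cols_present] = (np.arange(len(cols_present)) // block) % max(n_groups, 1)
        for k in range(n_groups):
            slab = m & (block_of_col[None, :] == k)
            gid = f"{gid_counter:02d}"
            gid_counter += 1
            poly = _cells_to_polygon(slab, stack.grid)
            groups.append(LanguageGroup(gid, family, poly, name=f"{name}_{gid}"))
            n_vill = int(rng.integers(config.villages_per_group[0],
                                      config.villages_per_group[1] + 1))
            villages[gid] = _sample_in_polygon(poly, n_vill, rng)
            tn = np.where(m, 1.0, 0.0)
            true_niches[gid] = SuitabilityMap(gid, stack.grid, tn,
                                              stack.shared_mask.copy())
            planted[gid] = name
    return SyntheticWorld(config, stack, groups, villages, true_niches,
                          planted, bounds)


def _sample_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < 500:
        m = max(4 * (n - len(pts)), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = contains_xy(poly, xs, ys)
        pts.extend(zip(xs[inside], ys[inside]))
        tries += 1
    if len(pts) < n:
        raise RuntimeError("could not place villages inside polygon")
    return np.array(pts[:n])


def generate_world(config: SyntheticWorldConfig | None = None) -> SyntheticWorld:
    """Full synthetic world: climate + DEM -> 26-layer stack -> groups."""
    config = config or SyntheticWorldConfig()
    tmin, tmax, prec, dem = generate_climate_dem(config)
    stack = assemble_stack(tmin, tmax, prec, dem)
    return plant_language_world(stack, config)


# ---------------------------------------------------------------------------
# Packaged printed-table fixture (ELP membership and group metadata)

def load_published_elp_table() -> tuple[list[ELPRecord], pd.DataFrame]:
    """The transcribed pattern-membership table and per-group metadata.

    Returns (records, metadata): 17 pattern records with region notes, member
    ids, families and printed language totals; and a frame indexed by
    group_id with the family and, for single-group patterns, the group's
    language count (multi-group patterns print only the total).
    """
    with resources.files("elnm.data").joinpath("published_elps.csv").open() as fh:
        table = pd.read_csv(fh, dtype={"member_ids": str})
    records = []
    meta_rows = []
    for _, row in table.iterrows():
        members = row["member_ids"].split(";")
        families = [f.strip() for f in row["families"].split(",")]
        records.append(ELPRecord(
            elp_label=row["elp_label"],
            member_ids=members,
            families=families,
            n_groups=int(row["n_groups"]),
            n_languages=int(row["n_languages"]),
            region_note=row["region"],
        ))
        for m in members:
            meta_rows.append({
                "group_id": m,
                "family": "TNG" if int(m) <= 29 else "Austronesian",
                "elp_label": row["elp_label"],
                "n_languages": int(row["n_languages"]) if len(members) == 1 else np.nan,
            })
    metadata = pd.DataFrame(meta_rows).set_index("group_id")
    return records, metadata
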