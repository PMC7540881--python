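"""Terrain derivatives from a digital elevation model.

Six layers per 3x3 moving window: Slope and Aspect by Horn's 8-neighbour
finite differences, Terrain Ruggedness Index (TRI), Topographic Position
Index (TPI), Roughness (window max - min), and a D8 flow-direction code.

Conventions (the field offers several; these are fixed and documented):

* Aspect is the azimuth of steepest *descent*, degrees clockwise from north,
  in [0, 360); flat cells (zero gradient) get aspect 0.
* Flowdir uses ESRI D8 codes (1=E, 2=SE, 4=S, 8=SW, 16=W, 32=NW, 64=N,
  128=NE), steepest descent with diagonal drops divided by sqrt(2); cells
  with no lower neighbour (pits/flats) get code 0.
* ``xy_scale`` converts cell size to the DEM's vertical units for the slope
  computation; the default 1.0 treats one cell as one horizontal unit.
* Border cells and any window touching nodata are masked.
"""

from __future__ import annotations

import numpy as np

from .raster import EnvStack, Layer

# neighbour offsets in Horn/D8 order around the window
#   z1 z2 z3        NW N NE
#   z4 z5 z6   =    W  C  E
#   z7 z8 z9        SW S SE
_D8_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_D8_CODES = {(0, 1): 1, (1, 1): 2, (1, 0): 4, (1, -1): 8,
             (0, -1): 16, (-1, -1): 32, (-1, 0): 64, (-1, 1): 128}


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """View of ``a`` shifted so index (r, c) holds a[r+dr, c+dc]; edges NaN."""
    out = np.full_like(a, np.nan)
    rs = slice(max(0, -dr), a.shape[0] - max(0, dr))
    cs = slice(max(0, -dc), a.shape[1] - max(0, dc))
    rs_src = slice(max(0, dr), a.shape[0] + min(0, dr))
    cs_src = slice(max(0, dc), a.shape[1] + min(0, dc))
    out[rs, cs] = a[rs_src, cs_src]
    return out


def terrain_derivatives(dem: Layer, xy_scale: float = 1.0) -> dict[str, Layer]:
    """Compute Slope, Aspect, Flowdir, TPI, TRI and Roughness from a DEM."""
    if dem.grid.n_rows < 3 or dem.grid.n_cols < 3:
        raise ValueError("terrain derivatives need at least a 3x3 DEM")
    z = dem.masked()

    nb = {off: _shift(z, *off) for off in _D8_OFFSETS}
    stack = np.stack(list(nb.values()))  # (8, r, c)
    center_ok = np.isfinite(z)
    window_ok = center_ok & np.all(np.isfinite(stack), axis=0)

    # Horn finite differences; cell size in horizontal units
    d = dem.grid.cell_size * xy_scale
    z1, z2, z3 = nb[(-1, -1)], nb[(-1, 0)], nb[(-1, 1)]
    z4, z6 = nb[(0, -1)], nb[(0, 1)]
    z7, z8, z9 = nb[(1, -1)], nb[(1, 0)], nb[(1, 1)]
    with np.errstate(invalid="ignore"):
        dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8 * d)
        dzdy = ((z1 + 2 * z2 + z3) - (z7 + 2 * z8 + z9)) / (8 * d)  # +north
        slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        # azimuth of the downslope vector (-dzdx east, -dzdy north)
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(slope == 0, 0.0, aspect)

    with np.errstate(invalid="ignore"):
        nb_mean = stack.mean(axis=0)
        tri = np.abs(stack - z[None]).mean(axis=0)
        tpi = z - nb_mean
        rough = np.maximum(stack.max(axis=0), z) - np.minimum(stack.min(axis=0), z)

    # D8 steepest descent: drop / distance, diagonals over sqrt(2)
    drops = []
    codes = []
    for off in _D8_OFFSETS:
        dist = np.sqrt(2.0) if off[0] != 0 and off[1] != 0 else 1.0
        drops.append((z - nb[off]) / dist)
        codes.append(_D8_CODES[off])
    drops = np.stack(drops)
    with np.errstate(invalid="ignore"):
        best = np.nanargmax(np.where(np.isfinite(drops), drops, -np.inf), axis=0)
        best_drop = np.take_along_axis(drops, best[None], axis=0)[0]
    flowdir = np.array(codes, dtype=float)[best]
    flowdir = np.where(best_drop > 0, flowdir, 0.0)

    mask = ~window_ok
    out = {}
    for name, vals in [("Slope", slope), ("Aspect", aspect), ("Flowdir", flowdir),
                       ("TPI", tpi), ("TRI", tri), ("Roughness", rough)]:
        v = np.where(mask, 0.0, vals)
        out[name] = Layer(dem.grid, v, mask.copy(), name)
    return out


def add_terrain(stack: EnvStack, dem: Layer, xy_scale: float = 1.0) -> EnvStack:
    """Add the DEM and its six derivatives to a stack."""
    stack.add("DEM", dem)
    for name, layer in terrain_derivatives(dem, xy_scale=xy_scale).items():
        stack.add(name, layer)
    return stack
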