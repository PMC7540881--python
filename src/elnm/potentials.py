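"""Family-level eco-linguistic potential, the delta-ELN differential map,
and growing-season / ecological-risk grids.

The eco-linguistic potential of a language family at a cell is the mean
suitability over all of the family's modelled niches (the divisor is the
family's total group count, so groups finding the cell unsuitable pull the
mean down).  The differential map is

    delta_ELN = mean(TNG niches) - mean(Austronesian niches),

bounded in [-1, 1]: positive where the environment favours one family's
niches over the other's.

The growing season (GS) of a cell counts the months in which vegetation can
grow under Le Houerou's rule: mean temperature strictly above 6 deg C and
monthly precipitation (mm) strictly more than twice the mean temperature
(deg C).  Ecological risk of a region is the reciprocal of its mean growing
season (MGS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import SuitabilityMap
from .raster import Grid, Layer

GS_TEMP_MIN_C = 6.0
GS_PREC_FACTOR = 2.0


@dataclass
class FamilyPotential:
    family: str
    values: np.ndarray            # mean suitability in [0, 1]
    nodata_mask: np.ndarray
    grid: Grid
    n_groups: int


@dataclass
class DeltaMap:
    grid: Grid
    values: np.ndarray            # in [-1, 1]
    nodata_mask: np.ndarray


def eco_linguistic_potential(elns: list[SuitabilityMap], family: str) -> FamilyPotential:
    """Cellwise mean suitability over all of a family's niches."""
    if not elns:
        raise ValueError("family has no niches")
    grid = elns[0].grid
    mask = np.zeros(grid.shape, bool)
    total = np.zeros(grid.shape)
    for m in elns:
        if m.grid != grid:
            raise ValueError("all niches must share a grid")
        total += m.values
        mask |= m.nodata_mask
    return FamilyPotential(family, total / len(elns), mask, grid, len(elns))


def delta_eln(tng: FamilyPotential, austro: FamilyPotential) -> DeltaMap:
    """TNG potential minus Austronesian potential, cellwise."""
    if tng.grid != austro.grid:
        raise ValueError("potentials must share a grid")
    return DeltaMap(tng.grid, tng.values - austro.values,
                    tng.nodata_mask | austro.nodata_mask)


def growing_season(tmean: list[Layer], prec: list[Layer]) -> Layer:
    """Months per cell satisfying the growing-season rule (0-12).

    Both inequalities are strict; the precipitation condition is evaluated
    multiplicatively (prec > 2 * tmean) so freezing months need no division.
    """
    if len(tmean) != 12 or len(prec) != 12:
        raise ValueError("need 12 monthly tmean and prec layers")
    grid = tmean[0].grid
    mask = np.zeros(grid.shape, bool)
    count = np.zeros(grid.shape)
    for t, p in zip(tmean, prec):
        mask |= t.nodata_mask | p.nodata_mask
        ok = (t.values > GS_TEMP_MIN_C) & (p.values > GS_PREC_FACTOR * t.values)
        count += ok
    return Layer(grid, np.where(mask, 0.0, count), mask, "GS")


def ecological_risk(gs: Layer, region_mask: np.ndarray | None = None
                    ) -> tuple[float, float | None]:
    """(MGS, risk) over a region; risk is None (undefined) when MGS is 0."""
    sel = gs.valid if region_mask is None else (gs.valid & region_mask)
    if not sel.any():
        raise ValueError("empty region")
    mgs = float(gs.values[sel].mean())
    risk = (1.0 / mgs) if mgs > 0 else None
    return mgs, risk
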