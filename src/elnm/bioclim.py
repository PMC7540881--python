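"""Derivation of the 19 bioclimatic variables from monthly climate.

Follows the standard ANUCLIM definitions used by the WorldClim family of
datasets, computed from 12 monthly minimum/maximum temperature grids (deg C)
and 12 monthly precipitation grids (mm).  Quarters are any 3 consecutive
months and wrap across the year boundary (Dec-Jan-Feb is a quarter).

Conventions where the definitions leave room:

* bio4 and bio15 use the sample standard deviation (ddof=1), matching the
  widely used dismo::biovars implementation.
* bio3 (isothermality) is defined as 0 where bio7 == 0 (a constant-temperature
  climate has no annual range to normalize by).
* bio15 divides by the mean monthly precipitation; an all-dry cell (mean 0)
  gets bio15 = 0 by the same convention.
* Quarter ties are broken by the lowest starting-month index.
"""

from __future__ import annotations

import numpy as np

from .raster import EnvStack, Layer

N_QUARTERS = 12  # one per starting month, wrapping


def _stack_monthly(layers: list[Layer]) -> np.ndarray:
    """(12, n_rows, n_cols) array from a monthly series."""
    if len(layers) != 12:
        raise ValueError("need exactly 12 monthly layers")
    return np.stack([lyr.values for lyr in layers])


def _quarter_views(monthly: np.ndarray) -> np.ndarray:
    """(12, ...) array of 3-month sums starting at each month, wrapping."""
    ext = np.concatenate([monthly, monthly[:2]], axis=0)
    return np.stack([ext[q:q + 3].sum(axis=0) for q in range(12)])


def compute_bioclim(tmin: list[Layer], tmax: list[Layer],
                    prec: list[Layer]) -> dict[str, Layer]:
    """Return the 19 bio layers keyed ``bio1`` ... ``bio19``.

    Preconditions: tmin <= tmax cellwise and prec >= 0 on valid cells.
    """
    grid = tmin[0].grid
    tn = _stack_monthly(tmin)
    tx = _stack_monthly(tmax)
    pr = _stack_monthly(prec)
    mask = np.zeros(grid.shape, bool)
    for series in (tmin, tmax, prec):
        for lyr in series:
            mask |= lyr.nodata_mask
    valid = ~mask
    if np.any(tn[:, valid] > tx[:, valid]):
        raise ValueError("tmin exceeds tmax on some valid cells")
    if np.any(pr[:, valid] < 0):
        raise ValueError("negative precipitation on some valid cells")

    tavg = (tn + tx) / 2.0

    out: dict[str, np.ndarray] = {}
    out["bio1"] = tavg.mean(axis=0)
    out["bio2"] = (tx - tn).mean(axis=0)
    out["bio4"] = 100.0 * tavg.std(axis=0, ddof=1)
    out["bio5"] = tx.max(axis=0)
    out["bio6"] = tn.min(axis=0)
    out["bio7"] = out["bio5"] - out["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = 100.0 * out["bio2"] / out["bio7"]
    out["bio3"] = np.where(out["bio7"] == 0, 0.0, bio3)
    out["bio12"] = pr.sum(axis=0)
    out["bio13"] = pr.max(axis=0)
    out["bio14"] = pr.min(axis=0)
    pr_mean = pr.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bio15 = 100.0 * pr.std(axis=0, ddof=1) / pr_mean
    out["bio15"] = np.where(pr_mean == 0, 0.0, bio15)

    # quarter statistics: 3-month precip sums and temperature means
    q_prec = _quarter_views(pr)
    q_temp = _quarter_views(tavg) / 3.0
    wettest = q_prec.argmax(axis=0)   # argmax/argmin take the lowest index on ties
    driest = q_prec.argmin(axis=0)
    warmest = q_temp.argmax(axis=0)
    coldest = q_temp.argmin(axis=0)

    def pick(arr: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(arr, idx[None], axis=0)[0]

    out["bio8"] = pick(q_temp, wettest)
    out["bio9"] = pick(q_temp, driest)
    out["bio10"] = pick(q_temp, warmest)
    out["bio11"] = pick(q_temp, coldest)
    out["bio16"] = pick(q_prec, wettest)
    out["bio17"] = pick(q_prec, driest)
    out["bio18"] = pick(q_prec, warmest)
    out["bio19"] = pick(q_prec, coldest)

    layers = {}
    for name in [f"bio{i}" for i in range(1, 20)]:
        vals = np.where(mask, 0.0, out[name])
        layers[name] = Layer(grid, vals, mask.copy(), name)
    return layers


def monthly_mean_temperature(tmin: list[Layer], tmax: list[Layer]) -> list[Layer]:
    """Monthly mean temperature as (tmin + tmax) / 2, used when true monthly
    means are not provided."""
    out = []
    for i, (a, b) in enumerate(zip(tmin, tmax)):
        mask = a.nodata_mask | b.nodata_mask
        vals = np.where(mask, 0.0, (a.values + b.values) / 2.0)
        out.append(Layer(a.grid, vals, mask, f"tmean{i + 1:02d}"))
    return out


def add_bioclim(stack: EnvStack) -> EnvStack:
    """Derive bio1..bio19 from the stack's monthly series and add them."""
    for key in ("tmin", "tmax", "prec"):
        if key not in stack.monthly:
            raise KeyError(f"stack lacks monthly series {key!r}")
    for name, layer in compute_bioclim(stack.monthly["tmin"], stack.monthly["tmax"],
                                       stack.monthly["prec"]).items():
        stack.add(name, layer)
    return stack
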