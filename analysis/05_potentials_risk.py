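#!/usr/bin/env python
"""Stage 5 — family suitability differential and ecological risk.

Averages the consensus niches within each language family into an
eco-linguistic potential, maps their difference (positive where the
environment favours the TNG-like family over the Austronesian-like one),
derives the growing-season grid from monthly climate, and reports the mean
growing season and its reciprocal, the ecological risk.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from elnm.bioclim import monthly_mean_temperature
from elnm.pipeline import PipelineConfig, run_pipeline
from elnm.potentials import ecological_risk, growing_season
from elnm.raster import Layer, write_raster


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/potentials"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    res = run_pipeline(PipelineConfig(seed=args.seed))
    args.out.mkdir(parents=True, exist_ok=True)
    stack = res.world.stack

    delta = res.delta
    lyr = Layer(delta.grid, np.where(delta.nodata_mask, 0.0, delta.values),
                delta.nodata_mask, "delta_eln")
    write_raster(lyr, args.out / "delta_eln.asc")
    valid = ~delta.nodata_mask
    pos = float((delta.values[valid] > 0).mean())

    tmean = monthly_mean_temperature(stack.monthly["tmin"], stack.monthly["tmax"])
    gs = growing_season(tmean, stack.monthly["prec"])
    write_raster(gs, args.out / "growing_season.asc")
    mgs, risk = ecological_risk(gs)

    print(f"delta map: range [{delta.values[valid].min():+.3f}, "
          f"{delta.values[valid].max():+.3f}]; "
          f"{100 * pos:.1f}% of land favours the TNG-like family")
    print(f"growing season: mean {mgs:.2f} months over "
          f"{int(valid.sum())} land cells; ecological risk = "
          f"{'1/%.2f = %.4f' % (mgs, risk) if risk else 'undefined'}")
    print(f"rasters in {args.out}/")


if __name__ == "__main__":
    main()
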