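#!/usr/bin/env python
"""Stage 1 — generate the synthetic island and its language groups.

Builds the default 200x200 world: stepped-plateau island, monthly climate,
the 26-layer environmental stack, eight language territories planted in five
environmental strata, and villages inside each territory.  Writes the stack
as text rasters plus the village table under results/world/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from elnm.raster import write_raster
from elnm.synthetic import SyntheticWorldConfig, generate_world


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/world"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")

    world = generate_world(SyntheticWorldConfig(seed=args.seed))
    args.out.mkdir(parents=True, exist_ok=True)

    for name in world.stack.names:
        write_raster(world.stack[name], args.out / f"{name}.asc")
    rows = [{"id": f"{gid}_{i:03d}", "lon": p[0], "lat": p[1], "group_id": gid}
            for gid, pts in world.villages.items() for i, p in enumerate(pts)]
    pd.DataFrame(rows).to_csv(args.out / "villages.csv", index=False)
    meta = pd.DataFrame(
        [{"group_id": g.group_id, "family": g.family,
          "stratum": world.planted_elps[g.group_id],
          "n_villages": len(world.villages[g.group_id])}
         for g in world.groups])
    meta.to_csv(args.out / "groups.csv", index=False)

    land = int((~world.stack.shared_mask).sum())
    print(f"world: {world.stack.grid.shape} grid, {land} land cells")
    print(meta.to_string(index=False))
    print(f"layers + villages written to {args.out}/")


if __name__ == "__main__":
    main()
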