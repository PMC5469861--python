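#!/usr/bin/env python
"""Generate the synthetic study system used by every downstream step.

Writes the four input tables (forest inventory, soil layers, community
cover + species attributes, landscape areas implicit in the ground-truth
sidecar) to results/data/.
"""

import argparse
from pathlib import Path

from punastocks import SimConfig, simulate_all

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/data"))
args = ap.parse_args()

cfg = SimConfig(seed=args.seed)
sim = simulate_all(cfg, args.outdir)
print(f"wrote {len(sim['inventory'])} tree records, "
      f"{sim['soil_layers']['profile_id'].nunique()} soil profiles, "
      f"{sim['cover'].shape[0]} vegetation plots x "
      f"{sim['cover'].shape[1]} species -> {args.outdir}")
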