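#!/usr/bin/env python
"""Generate the synthetic cruise and satellite fields on disk.

Writes CSV casts/nutrients/tows and NetCDF SSH/velocity/POC grids to
scratch/fixtures/ (binary grids are scratch output, not deliverables),
so later stages and the CLI can be exercised file-to-file.
"""

import argparse
from pathlib import Path

import numpy as np

from gomflux import cli_io as io
from gomflux.synthetic_data import (SimulationConfig, gen_density_profiles,
                                    gen_nutrient_profiles, gen_surface_fields,
                                    gen_tow_pair)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out-dir", type=Path, default=Path("scratch/fixtures"))
args = ap.parse_args()

cfg = SimulationConfig(seed=args.seed)
out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

casts, truths = gen_density_profiles(cfg)
io.write_casts_csv(out / "casts.csv", casts)
n_injected = sum(len(t) for t in truths)
print(f"{len(casts)} CTD casts written; {n_injected} overturns injected "
      f"({cfg.overturn_height_range[0]}-{cfg.overturn_height_range[1]} m tall)")

no3, nh4 = gen_nutrient_profiles(cfg)
io.write_nutrients_csv(out / "nutrients.csv", [no3, nh4])
print(f"nitrate: {no3.conc[no3.depth <= 60].mean():.0f} umol m-3 in the UEZ, "
      f"{no3.conc[-1]:.0f} at {no3.depth[-1]:.0f} m; "
      f"ammonium mean {nh4.conc.mean():.0f} umol m-3")

day, night, migrant = gen_tow_pair(cfg)
io.write_tows_csv(out / "tows.csv", [day, night])
print(f"paired tows: migrant carbon {migrant.sum():.0f} mg C m-2 across "
      f"{migrant.size} size classes")

ssh, vel, poc = gen_surface_fields(cfg)
io.write_grid(out / "ssh.nc", ssh)
io.write_grid(out / "velocity.nc", vel)
io.write_grid(out / "poc.nc", poc)
print(f"surface fields: {poc.time.size} composites on a "
      f"{poc.lat.size}x{poc.lon.size} tracer grid; "
      f"max speed {np.hypot(vel.u, vel.v).max():.2f} m/s; "
      f"POC {np.nanmin(poc.tracer):.2f}-{np.nanmax(poc.tracer):.2f} mmol C m-3")
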