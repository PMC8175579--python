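#!/usr/bin/env python
"""Lateral PON transport into the offshore control volume.

POC composites are converted to PON (Redfield 106:16), binned to 8 km,
advected by the regridded surface currents, and the net boundary flux
per unit area is computed at every composite. Eddies are identified
from closed SSH contours and their boundary-flux share book-kept.
Writes results/lateral_flux.csv and results/eddies.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from gomflux import lateral_transport as lt
from gomflux.pipeline import default_control_volume
from gomflux.synthetic_data import SimulationConfig, gen_surface_fields

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(seed=args.seed)
ssh, vel, poc = gen_surface_fields(cfg)
cv = default_control_volume(cfg)

pon = lt.bin_tracer(lt.poc_to_pon(poc), cell_km=8.0)
series = lt.flux_series(pon, vel, cv)
stats = lt.flux_statistics(series)

pd.DataFrame({"time_days": series.time,
              "net_flux_umolN_m2_d": series.net_flux_per_area}
             ).to_csv(args.out_dir / "lateral_flux.csv", index=False)
print(f"control volume: {series.results[0].surface_area / 1e9:.0f} x 1e9 m2, "
      f"H = {cv.depth_extent:.0f} m, {len(series.results[0].edges)} boundary faces")
print(f"net lateral PON input: median {stats['median']:.0f} umol N m-2 d-1 "
      f"(IQR {stats['iqr'][0]:.0f}-{stats['iqr'][1]:.0f}, n={stats['n']})")

eddies = lt.detect_eddies(ssh, vel, levels_spacing=0.02, time_index=0)
attr = lt.eddy_flux_attribution(series.results[0], eddies, pon)
pd.DataFrame([{"center_lon": e.center_lon, "center_lat": e.center_lat,
               "mean_boundary_speed_m_s": e.mean_speed, "polarity": e.polarity}
              for e in eddies]).to_csv(args.out_dir / "eddies.csv", index=False)
print(f"{len(eddies)} mesoscale eddies at t=0; boundary cells inside eddies "
      f"carry {100 * attr['fraction_of_net']:.0f}% of the net flux")
print(f"wrote {args.out_dir / 'lateral_flux.csv'} and {args.out_dir / 'eddies.csv'}")
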