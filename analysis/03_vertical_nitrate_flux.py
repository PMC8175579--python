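#!/usr/bin/env python
"""Turbulent nitrate fluxes across the euphotic-zone boundaries.

Combines the geometric-mean diffusivity profile with OLS nitrate
gradients over 20-m windows at 60 m (UEZ base) and 110 m (euphotic-zone
base). Writes results/vertical_flux.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from gomflux.hydrography import (MixingParams, average_kz, cast_kz_profile,
                                 detect_overturns, layer_geomean,
                                 preprocess_profile, thorpe_displacements)
from gomflux.pipeline import (DEPTH_BIN_EDGES, GRADIENT_WINDOW, LEZ_BOUNDARY,
                              UEZ_BOUNDARY)
from gomflux.synthetic_data import (SimulationConfig, gen_density_profiles,
                                    gen_nutrient_profiles)
from gomflux.vertical_flux import diffusive_flux, layer_gradient

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out", type=Path, default=Path("results/vertical_flux.csv"))
args = ap.parse_args()
args.out.parent.mkdir(parents=True, exist_ok=True)

cfg = SimulationConfig(seed=args.seed)
params = MixingParams()
casts, _ = gen_density_profiles(cfg)
per_cast = []
for cast in casts:
    clean = preprocess_profile(cast, params)
    segs = detect_overturns(thorpe_displacements(clean), clean, params)
    per_cast.append(cast_kz_profile(segs, DEPTH_BIN_EDGES, params))
kz_prof = average_kz(per_cast, DEPTH_BIN_EDGES)

nitrate, _ = gen_nutrient_profiles(cfg)
rows = []
for name, boundary in (("UEZ", UEZ_BOUNDARY), ("LEZ", LEZ_BOUNDARY)):
    layer = (boundary - GRADIENT_WINDOW / 2, boundary + GRADIENT_WINDOW / 2)
    kz = layer_geomean(kz_prof, layer)
    est = diffusive_flux(kz, layer_gradient(nitrate, layer), layer)
    rows.append({"boundary": name, "layer_top_m": layer[0],
                 "layer_bottom_m": layer[1], "kz_m2_s": est.kz,
                 "gradient_umol_m4": est.gradient,
                 "flux_umolN_m2_d": est.flux})
    print(f"{name} boundary ({boundary:.0f} m): K_z {kz:.2e} m2/s, "
          f"gradient {est.gradient:.3g} umol m-4 -> "
          f"flux {est.flux:.3g} umol N m-2 d-1")

pd.DataFrame(rows).to_csv(args.out, index=False)
print(f"UEZ flux is ~0 (no gradient above the deep nitracline); "
      f"the LEZ flux is orders of magnitude below measured export.")
print(f"wrote {args.out}")
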