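#!/usr/bin/env python
"""Payback times for BECCS and the grid-cell forest-vs-BECCS contest.

Payback (recovery) time is the carbon deficit a cell accumulated under
conversion to bioenergy crops divided by its mean annual flux into the
geological reservoir.  Expect zero payback where bioenergy replaced
existing farmland (moderate scenario, temperate belt) and recovery beyond
a century where it replaced high-soil-carbon boreal/tundra ecosystems
(ambitious scenario).  The winning fraction -- the share of conflict
cells where BECCS out-stores the forest by 2100 -- is swept over capture
multipliers (1, 1.5, 2, 3) and recomputed under the accounting variant
that credits the initially cleared biomass to the reservoir.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from landmit import attribution as att
from landmit.grid import BIOMES
from landmit.pipeline import StudyContext, run_single

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

ctx = StudyContext.build(n_lat=36, n_lon=48, n_members=8, seed=1)
member = ctx.members[0]

rows = []
paybacks = {}
for exp, preset in [("1.5C_IM19", "im19_like"), ("2C_IM26", "im26_like")]:
    r = run_single(ctx, exp, member)
    traj = ctx.trajectories[preset]
    led = att.categorize_luc(traj, att.annual_stock_change(r))
    pb = att.payback_time(led, r, traj)
    paybacks[exp] = (r, traj, led, pb)
    rec = pb.recovery_years[pb.has_bioenergy]
    rows.append(
        {
            "experiment": exp,
            "bioenergy_cells": int(pb.has_bioenergy.sum()),
            "zero_recovery": int(np.sum(rec == 0)),
            "over_100yr": int(np.sum(rec > 100)),
            "median_recovery_yr": float(np.median(rec)),
        }
    )
    cells = np.flatnonzero(pb.has_bioenergy)
    pd.DataFrame(
        {
            "cell": cells,
            "biome": [BIOMES[b] for b in ctx.biome_ids[cells]],
            "lat": ctx.grid.lat_center[cells],
            "deficit_kg_m2": pb.deficit[cells],
            "mean_flux_kg_m2_yr": pb.mean_flux[cells],
            "recovery_years": pb.recovery_years[cells],
        }
    ).to_csv(RESULTS / f"payback_{exp}.csv", index=False)
print(pd.DataFrame(rows).to_string(index=False))

# forest-vs-BECCS contest on conflict cells (ambitious bioenergy vs the
# moderate scenario's retained/regrowing forests, same 1.5 C climate)
r_bio, traj_bio, led_bio, _ = paybacks["1.5C_IM19"]
r_for = run_single(ctx, "1.5C_IM26", member)
traj_for = ctx.trajectories["im26_like"]
led_for = att.categorize_luc(traj_for, att.annual_stock_change(r_for))
comp = att.compare_forest_vs_beccs(r_bio, r_for, traj_bio, traj_for, led_bio, led_for)

cfg_var = replace(ctx.config, initial_biomass_to_beccs=True)
r_var = run_single(ctx, "1.5C_IM19", member, cfg_var)
led_var = att.categorize_luc(traj_bio, att.annual_stock_change(r_var))
comp_var = att.compare_forest_vs_beccs(
    r_var, r_for, traj_bio, traj_for, led_var, led_for
)

curve = comp.curve.merge(
    comp_var.curve, on="multiplier", suffixes=("", "_initial_biomass_to_beccs")
)
curve.to_csv(RESULTS / "winning_fraction.csv", index=False)
print(f"\nconflict cells: {int(comp.conflict_cells.sum())}")
print(curve.to_string(index=False))
print("\ncrediting the initially cleared biomass to the reservoir raises the"
      " winning fraction at every multiplier" if
      (curve.iloc[:, 2] >= curve.iloc[:, 1]).all() else "")
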