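# landmit

Reduced-complexity carbon accounting for land-based climate mitigation:
what happens to land carbon when ambitious warming targets are pursued
with large-scale bioenergy crops plus carbon capture and storage (BECCS),
afforestation/reforestation, and avoided deforestation?

Integrated-assessment scenarios that hold warming near 1.5 °C lean heavily
on BECCS: hundreds of Mha of bioenergy crops whose harvested carbon is
combusted for energy and pumped into geological storage. Whether that
actually removes CO₂ from the atmosphere depends on what the crops
replaced — clearing a high-carbon forest or a carbon-rich boreal soil can
put more carbon into the air than decades of capture bring back. `landmit`
is a desk-scale pipeline for exploring exactly that question: a gridded
vegetation/soil/wood-product bookkeeping model with explicit BECCS
capture, driven by synthetic land-use and climate scenarios, with the
attribution, payback-time and forest-vs-BECCS analyses needed to compare
mitigation strategies. It is aimed at carbon-cycle researchers and
students who want a transparent, fully testable sandbox rather than a
full Earth-system model.

## The model in brief

Each land cell carries plant functional types (PFTs) with areal fraction
ν and carbon density C_veg. NPP accumulated over a step (Π) closes the
vegetation carbon balance through the litter flux

    Λ = Π ν_{n−1} − (C_veg ν − C_veg,n−1 ν_{n−1})

Litter feeds a four-pool soil model with Q10 temperature sensitivity.
A fraction ε_harv = 0.3 of crop litter is harvested; the bioenergy share
ν_bio/ν_agric of the harvest is diverted to a non-decaying geological
reservoir with transfer efficiency ε_BECCS = 0.6,

    BECCS = H_i (ν_bio / ν_agric) ε_BECCS ,   H = H_i − BECCS ,

the remainder entering a fast (1-yr) wood-product pool. Land cleared of
woody vegetation routes its aboveground biomass 60/30/10 % into fast
(1 yr) / medium (10 yr) / slow (100 yr) product pools, belowground carbon
into the fast soil pool. Climate forcing comes from inverting a two-box
energy-balance model: a prescribed warming path (asymptoting to 1.5 or
2 °C by 2100) plus each ensemble member's climate feedback λ yields the
radiative forcing and, through the logarithmic law
CO₂ = CO₂_pre · 2^(Q_co2/F_2x), a member-specific CO₂ path; local
anomalies are pattern-scaled. See `docs/methods.md` for assumptions,
parameters and limitations.

## Worked example

```python
from landmit.pipeline import StudyContext, run_matrix, summarize

ctx = StudyContext.build(n_lat=36, n_lon=48, n_members=8, seed=1)
print(summarize(run_matrix(ctx)).round(1).to_string(index=False))
```

```
    experiment  n_members  dC_veg_mean  dC_veg_sd  dC_soil_mean  dC_soil_sd  beccs_cum_mean  beccs_cum_sd  dC_total_mean  dC_total_sd
     1.5C_IM19          8          7.5        3.7           2.4         4.2            22.5           0.2           34.1          8.2
     1.5C_IM26          8         17.6        3.8           9.4         4.3            12.7           0.1           41.0          8.2
       2C_IM19          8         28.5        7.5          10.5         7.6            23.7           0.4           64.4         15.4
       2C_IM26          8         39.0        7.7          17.6         7.7            13.4           0.2           71.4         15.6
2C_IM26_1.5CO2          8         20.1        4.3          -3.6         3.9            12.9           0.1           30.7          8.2
```

Each row is one experiment (land-use preset × warming target, plus the
variant that keeps 2 °C warming but the 1.5 °C CO₂ path), ensemble mean
± sd in GtC over 2000–2100. The headline: total land carbon (vegetation
+ soil + products + geological storage) gains *less* in the ambitious
`1.5C_IM19` world (+34 GtC) than in the moderate `2C_IM26` world
(+71 GtC) — the extra land converted to bioenergy crops loses more
carbon than the ~10 GtC of additional BECCS capture brings back, and the
lower CO₂ path fertilizes vegetation less. The numbered scripts under
`analysis/` walk through the full story: input synthesis, the experiment
matrix, the five-way attribution of the difference, and the payback /
forest-vs-BECCS comparison. A CLI wraps the same steps
(`landmit synth|simulate|attribute|compare|report`).

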