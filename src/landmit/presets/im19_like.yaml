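# Ambitious-mitigation land-use preset: large bioenergy expansion peaking
# at 550 Mha in 2060 and declining to 430 Mha by 2100, weighted toward
# mid/high latitudes (a caricature of where the integrated-assessment
# scenario places plantations, not a reproduction of its maps).
name: im19_like
start_year: 2030
peak_year: 2060
peak_area_mha: 550.0
end_area_mha: 430.0
lat_center: 52.0
lat_sd: 14.0
agri_displacement: 0.25
bio_cap: 0.6
crop_area_mha: 1500.0
pasture_area_mha: 3300.0
seed: 0
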