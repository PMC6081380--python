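# Moderate-mitigation land-use preset: smaller bioenergy expansion peaking
# at 325 Mha in 2085, weighted toward temperate latitudes and placed
# predominantly on existing and abandoned agricultural land (fully
# displaceable before any natural vegetation is cleared).
name: im26_like
start_year: 2030
peak_year: 2085
peak_area_mha: 325.0
end_area_mha: 310.0
lat_center: 44.0
lat_sd: 10.0
agri_displacement: 1.0
bio_cap: 0.6
crop_area_mha: 1500.0
pasture_area_mha: 3300.0
seed: 0
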