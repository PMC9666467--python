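regime: dispersal_limitation
n_stations: 26
n_depths: 1
n_size_fractions: 1
lat_range:
- -52.1
- 58.9
longitude: 180.0
temperature_peak: 29.0
temperature_polar_min: 2.0
temperature_width: 20.0
n_taxa: 200
metacommunity_mean: 0.0
metacommunity_sd: 1.5
brownian_rate: 64.0
trait_root: 15.5
sigma_w: null
dispersal_scale: 1500.0
community_size: 100000
local_noise_sd: 0.0
read_depth: 8000
n_regions: 5
region_pool_sd: 2.0
birth_rate: 1.0
death_rate: 0.8
seed: 0
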