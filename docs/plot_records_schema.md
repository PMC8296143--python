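# Plot-records CSV schema

One row per plot-year of the augmented field trial.  Dates are integer day
offsets from sowing.  The two dated measurement series are stored as JSON
arrays inside their columns; all other columns are scalars.

| column | type | meaning |
|---|---|---|
| `year` | int | trial year |
| `plot` | int | plot number within the year (1-based, serpentine order) |
| `row`, `col` | int | grid coordinates of the plot |
| `genotype` | str | genotype name (checks carry the check-cultivar name) |
| `is_check` | bool | replicated check plot |
| `gs11`, `gs55`, `gs65`, `gs87` | int | emergence, heading, anthesis, maturity (days from sowing; empty = not recorded) |
| `par_samples` | JSON `[[day, PAR_i, PAR_t, PAR_r], ...]` | ceptometer triplets: incident, transmitted, reflected flux (shared units); `day` may be fractional |
| `incident_par_daily` | float | incident PAR, MJ m⁻² day⁻¹, used to cumulate absorbed PAR |
| `dm_a_sample_g` | float | oven-dry mass (g) of the anthesis biomass cut |
| `dm_sample_row_length_m` | float | length of the sampled row section for the biomass cut (default 0.5) |
| `ta_anthesis`, `ta_milky` | float | air temperature (°C) at the two CTD occasions |
| `tc_anthesis`, `tc_milky` | JSON `[t1, t2, t3]` | three canopy-temperature readings (°C) per occasion |
| `ga_samples` | JSON `[[day, GA], ...]` | green-area estimates from plot images |
| `harvest_row_length_m`, `row_spacing_m` | float | geometry of the pre-harvest 1 m row sample (defaults 1.0, 0.15) |
| `spikes`, `grains` | float | spike and grain counts of the row sample |
| `grain_mass_g`, `total_mass_g` | float | grain and whole-plant mass (g) of the row sample |
| `subsample_mass_g`, `subsample_grain_count` | float | grain-weight subsample drawn from the harvested grain |
| `ph_cm`, `pl_cm` | JSON `[v1, v2, v3]` | plant height / peduncle length on three main stems (cm) |
| `plot_yield_kg` | float | machine-harvested plot yield (kg) |
| `plot_area_m2` | float | plot area (default 3.6) |
| `moisture_factor` | float | multiplicative standardization factor to the 12 % moisture basis (1.0 = already standardized) |

Counts are stored as floats: the generator inverts target trait values into
raw measurements exactly, and integer rounding of counts would break the
round trip.  Missing scalar measurements are empty cells and propagate to
missing trait values, never to zeros.
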