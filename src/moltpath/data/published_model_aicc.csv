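# AICc values of the published candidate PGLS model sets for the 48-species
# warbler dataset (one block per response variable), used to verify the
# Akaike-weight arithmetic against the printed weight column.
response,model,aicc
sd_extent,pa_extent + stratum_winter,115.9
sd_extent,pa_extent + stratum_breeding,116
sd_extent,pa_extent + stratum_winter + day_length,117
sd_extent,pa_extent + stratum_winter + stratum_breeding,117.9
sd_extent,pa_extent,120.4
sd_extent,migration_distance + stratum_breeding,131
sd_extent,migration_distance + stratum_winter,131.8
sd_extent,migration_distance + stratum_breeding + stratum_winter,132.7
sd_extent,stratum_winter + breeding_mean_temperature,133.1
sd_extent,stratum_winter,134.1
sd_extent,stratum_breeding,134.3
sd_extent,migration_distance,134.5
sd_extent,day_length,134.8
sd_extent,breeding_min_temperature,134.9
sd_extent,migration_distance_alt,135.2
pa_extent,migration_distance + day_length + breeding_solar_radiation,173.8
pa_extent,day_length + breeding_solar_radiation,175.8
pa_extent,migration_distance,176.7
pa_extent,migration_distance + breeding_solar_radiation,177
pa_extent,day_length + migration_distance,177.8
pa_extent,day_length + breeding_solar_radiation + solar_radiation,178
pa_extent,migration_distance + winter_solar_radiation,178.3
pa_extent,day_length,178.7
pa_extent,migration_distance + winter_solar_radiation_alt,178.9
pa_extent,day_length + solar_radiation,178.9
pa_extent,migration_distance + solar_radiation,179
pa_extent,day_length + breeding_precipitation,180
pa_extent,day_length + winter_solar_radiation,180.2
pa_extent,day_length + stratum_breeding + stratum_winter + breeding_solar_radiation,180.3
pa_extent,day_length + breeding_min_temperature,180.5
pa_extent,day_length + stratum_breeding,180.5
pa_extent,day_length + stratum_winter,182.9
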