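# Replication experiment: ambulance response vs bystander AED round trip
# on a synthetic city-center grid.
#
# Stated study parameters: 50 demand points, one ambulance station,
# 300 s coverage budget (150 s per walking stretch), bystander speed
# 10 km/h, ambulance speed 50 km/h, 18 AED sites. City geometry and the
# candidate pool are synthetic choices (see docs/methods.md): a 25x25
# grid of 200 m blocks (~4.8 km square, city-center scale), demand in
# the central half of the bounding box, 150 candidate corners.
city:
  rows: 25
  cols: 25
  block_m: 200.0
  jitter_m: 15.0
  oneway_fraction: 0.3
  n_demand: 50
  n_candidates: 150
  n_stations: 1
  center_fraction: 0.5
  seed: 0            # overridden by the experiment seed
threshold_s: 300.0
walk_speed_kmh: 10.0
ambulance_speed_kmh: 50.0
station_position: corner
mclp_mode: fixed_p   # the study's 18 sites may also be read as
p: 18                # min_for_target at the achieved coverage; both
target_fraction: 0.94  # workflows are supported (47/50 = 0.94)
solver: greedy
ci_method: t
exact_limit: 25
continuity: false
seed: 0
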