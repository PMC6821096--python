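# Data dictionary

All tables are CSV (header row, UTF-8, `.` decimal). XLSX versions of the
same tables are accepted read-only. Distances within tables are meters
unless the column name says otherwise.

## Segment table (`segments.csv`) — one row per transect segment

| column | type | meaning |
|---|---|---|
| `segment_id` | int | unique segment identifier |
| `transect_id` | int | parent transect |
| `region` | cat | `park_west`, `park_east`, `gma` |
| `side` | cat | side of the river: `west`, `east` |
| `area` | cat | protection level: `park`, `gma` |
| `length_km` | float | segment length (km), at most 2 |
| `x_mid`, `y_mid` | float | planar midpoint coordinates (m) |
| `edge_density` | float | cover-type edge density in the segment buffer (km/km^2) |
| `pct_closed_scrub` | float | % of buffer in closed scrubland |
| `pct_closed_woodland` | float | % closed woodland |
| `pct_open_woodland` | float | % open woodland |
| `pct_open_grassland` | float | % open grassland |
| `lion_ud` | float | predator utilization at the midpoint (raw scale) |
| `dist_roads_km` | float | distance to nearest road (km) |
| `dist_river_km` | float | distance to the perennial river (km) |
| `dist_stream_km` | float | distance to nearest seasonal stream (km) |
| `veg_class` | cat | six-level vegetation structure class |
| `veg_class3` | cat | simplified class: `scrub`, `woodland`, `grassland` |
| `path_type` | cat | `off_road`, `seasonal_track`, `gravel_road` |

## Occasion table (`occasions.csv`) — one row per segment x survey occasion

| column | type | meaning |
|---|---|---|
| `segment_id`, `occasion` | int | key |
| `year` | int | survey year |
| `season_stage` | cat | `early`, `mid`, `late` dry season |
| `survey_day` | float | days since the start of the dry season |
| `grass_height` | cat | `short`, `intermediate`, `tall` |
| `grass_color` | cat | `green`, `brown` |
| `burn` | cat | burn evidence: `present`, `absent` |
| `water` | cat | standing water: `present`, `absent` |
| `lagoon` | cat | grassy lagoon: `present`, `absent` |

## Detection table (`detections.csv`) — one row per detected herd

| column | type | meaning |
|---|---|---|
| `species` | cat | species label (multi-species tables) |
| `segment_id`, `occasion` | int | where and when |
| `distance_m` | float | perpendicular distance from the line (m), continuous |
| `size` | int | herd size, >= 1 |

## Location table (relocations) — one row per animal fix

| column | type | meaning |
|---|---|---|
| `animal_id` | int | animal |
| `fix` | int | fix number (one per day) |
| `x`, `y` | float | planar coordinates (m) |
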