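"""Generate a synthetic mountain reserve: relief, climate layers, zoning, roads.

The landscape emulates a ~142 km^2 montane reserve with 375-2,118 m relief,
elevation-driven climate in annual/summer/winter groups, nested
core/buffer/experimental zoning and valley roads.
"""

from gapstack import generate_landscape, generate_zones_and_roads

land = generate_landscape(seed=7)
zones, roads = generate_zones_and_roads(land, seed=7)

print(f"grid: {land.grid.nrows} x {land.grid.ncols} cells "
      f"({land.grid.cell_size:.0f} m), {land.grid.area_km2:.2f} km2")
print(f"elevation: {land.elevation.min():.0f}-{land.elevation.max():.0f} m, "
      f"max slope {land.slope.max():.1f} deg")
for name, (layer, season) in land.climate.items():
    print(f"  {name:12s} [{season:6s}] {layer.min():8.1f} .. {layer.max():8.1f}")
print("zone areas (km2):", {k: round(v, 2) for k, v in zones.zone_areas().items()})
print(f"roads: {len(roads)} polylines, total {sum(r.length for r in roads)/1000:.1f} km")
# Zone areas keep the emulated reserve's core:buffer:experimental proportions;
# the outside band leaves room for the 1-km margin ring used in gap analysis.
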