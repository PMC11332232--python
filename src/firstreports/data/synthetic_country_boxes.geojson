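{
  "type": "FeatureCollection",
  "name": "synthetic_country_boxes",
  "description": "SYNTHETIC rectangular stand-ins for country boundaries (WGS84 decimal degrees). Not real borders; used for point-in-polygon tests and for anchoring the synthetic report generator.",
  "features": [
    {"type": "Feature", "properties": {"name": "Spain", "kind": "country"},
     "geometry": {"type": "Polygon", "coordinates": [[[-10.0, 36.0], [-2.0, 36.0], [-2.0, 43.0], [-10.0, 43.0], [-10.0, 36.0]]]}},
    {"type": "Feature", "properties": {"name": "France", "kind": "country"},
     "geometry": {"type": "Polygon", "coordinates": [[[-1.0, 43.5], [7.0, 43.5], [7.0, 50.0], [-1.0, 50.0], [-1.0, 43.5]]]}},
    {"type": "Feature", "properties": {"name": "Italy", "kind": "country"},
     "geometry": {"type": "Polygon", "coordinates": [[[8.0, 37.0], [16.0, 37.0], [16.0, 43.0], [8.0, 43.0], [8.0, 37.0]]]}},
    {"type": "Feature", "properties": {"name": "Japan", "kind": "country"},
     "geometry": {"type": "Polygon", "coordinates": [[[130.0, 31.0], [144.0, 31.0], [144.0, 44.0], [130.0, 44.0], [130.0, 31.0]]]}},
    {"type": "Feature", "properties": {"name": "Australia", "kind": "country"},
     "geometry": {"type": "Polygon", "coordinates": [[[114.0, -38.0], [153.0, -38.0], [153.0, -12.0], [114.0, -12.0], [114.0, -38.0]]]}},
    {"type": "Feature", "properties": {"name": "Chile", "kind": "country"},
     "geometry": {"type": "Polygon", "coordinates": [[[-75.0, -55.0], [-67.0, -55.0], [-67.0, -18.0], [-75.0, -18.0], [-75.0, -55.0]]]}},
    {"type": "Feature", "properties": {"name": "Lake Centralis", "kind": "water"},
     "geometry": {"type": "Polygon", "coordinates": [[[20.0, 38.0], [24.0, 38.0], [24.0, 42.0], [20.0, 42.0], [20.0, 38.0]]]}}
  ]
}
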