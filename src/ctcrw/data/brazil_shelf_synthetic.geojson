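{
  "type": "FeatureCollection",
  "name": "brazil_shelf_synthetic",
  "description": "Synthetic proxy for the Brazilian continental shelf (~200 m isobath), hand-drawn; not survey data.",
  "features": [
    {
      "type": "Feature",
      "properties": {"name": "brazil_shelf_proxy", "synthetic": true},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[
          [-53.8, -34.5],
          [-53.5, -34.0],
          [-51.0, -31.0],
          [-48.5, -27.0],
          [-46.0, -24.0],
          [-43.0, -23.0],
          [-41.0, -22.0],
          [-39.5, -19.5],
          [-39.0, -16.0],
          [-38.8, -13.0],
          [-37.0, -10.0],
          [-35.0, -8.0],
          [-34.8, -6.0],
          [-34.5, -5.0],
          [-33.0, -5.0],
          [-33.5, -6.5],
          [-34.0, -9.0],
          [-36.0, -11.0],
          [-37.5, -13.5],
          [-37.2, -16.0],
          [-37.4, -18.5],
          [-39.3, -21.0],
          [-40.3, -22.6],
          [-44.0, -24.6],
          [-47.0, -27.6],
          [-49.5, -30.6],
          [-51.5, -34.6],
          [-52.5, -35.2],
          [-53.8, -34.5]
        ]]
      }
    }
  ]
}
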