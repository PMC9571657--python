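{
  "annotations": {
    "counts": "2 sepals, 2 petals, 3 outer + 2 inner petaloid staminodes, a dorsal fertile stamen with two thecae and a filamentous filament, 2 carpels",
    "style": "only slightly laminar"
  },
  "figures": [
    "4",
    "12A"
  ],
  "id": "Ci-1",
  "normal": false,
  "observed": {
    "0": {
      "appendage_side": "none",
      "locule_count": 2,
      "organ_states": [
        {
          "identity": "outer_staminode",
          "position_deg": 60,
          "state": "petaloid",
          "whorl": "outer_androecium"
        },
        {
          "identity": "outer_staminode",
          "position_deg": 180,
          "state": "petaloid",
          "whorl": "outer_androecium"
        },
        {
          "identity": "outer_staminode",
          "position_deg": 300,
          "state": "petaloid",
          "whorl": "outer_androecium"
        },
        {
          "identity": "fertile_stamen",
          "position_deg": 0,
          "state": "fertile",
          "whorl": "inner_androecium"
        },
        {
          "identity": "inner_staminode",
          "position_deg": 120,
          "state": "petaloid",
          "whorl": "inner_androecium"
        },
        {
          "identity": "inner_staminode",
          "position_deg": 240,
          "state": "petaloid",
          "whorl": "inner_androecium"
        }
      ],
      "petal_count": 2,
      "sepal_count": 2,
      "style_form": "laminar",
      "symmetry": "zygomorphic",
      "theca_count": 2,
      "zygomorphy_axis": "dorsoventral"
    }
  },
  "pf_class": "single_flower",
  "rule_exceptions": {},
  "species": "Canna indica",
  "topology": {
    "bract": null,
    "children": [
      {
        "bract": {
          "angle_deg": 180,
          "fused_with": null,
          "order_index": 1
        },
        "children": [],
        "handedness": null,
        "kind": "flower",
        "order": 1,
        "status": "mature"
      }
    ],
    "handedness": "sinistrorse",
    "kind": "axis",
    "order": 0,
    "status": "mature"
  },
  "version": "1.0"
}
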