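{
  "annotations": {
    "counts": "six petaloid staminodes dominate the display; 4-locular ovary",
    "interpretive": "secondary bracts placed 'more adaxial': transcribed at the adaxial-lateral sector (45/315 degrees)"
  },
  "figures": [
    "5C",
    "5D",
    "5E",
    "12D"
  ],
  "id": "Ci-3",
  "normal": false,
  "observed": {
    "0": {
      "appendage_side": "none",
      "locule_count": 4,
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
          "state": "petaloid",
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
      "petal_count": 4,
      "sepal_count": 4,
      "style_form": "filamentous",
      "symmetry": "zygomorphic",
      "theca_count": 0,
      "zygomorphy_axis": "dorsoventral"
    }
  },
  "pf_class": "cyme_1f",
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
        "children": [
          {
            "bract": {
              "angle_deg": 45,
              "fused_with": null,
              "order_index": 2
            },
            "children": [],
            "handedness": null,
            "kind": "flower",
            "order": 2,
            "status": "aborted"
          },
          {
            "bract": {
              "angle_deg": 315,
              "fused_with": null,
              "order_index": 2
            },
            "children": [],
            "handedness": null,
            "kind": "flower",
            "order": 2,
            "status": "aborted"
          }
        ],
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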