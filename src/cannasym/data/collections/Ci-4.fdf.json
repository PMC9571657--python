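{
  "annotations": {
    "interpretive": "the figure-view 'left abaxial' tertiary bract of the secondary flower maps to 225 degrees in that flower's own (rotated) frame",
    "secondary": "secondary flower has the normal mirrored (dextrorse-like) morphology",
    "staminodes": "one whorl of four petaloid staminodes; both lateral ones curved and spotted like labella; the adaxial one fully developed and bifid"
  },
  "figures": [
    "6",
    "12E"
  ],
  "id": "Ci-4",
  "normal": false,
  "observed": {
    "0": {
      "appendage_side": "none",
      "locule_count": 4,
      "organ_states": [
        {
          "identity": "outer_staminode",
          "position_deg": 0,
          "state": "petaloid",
          "whorl": "outer_androecium"
        },
        {
          "identity": "outer_staminode",
          "position_deg": 90,
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
          "position_deg": 270,
          "state": "petaloid",
          "whorl": "outer_androecium"
        }
      ],
      "petal_count": 2,
      "sepal_count": 2,
      "style_form": "filamentous",
      "symmetry": "zygomorphic",
      "theca_count": 0,
      "zygomorphy_axis": "dorsoventral"
    },
    "0/1": {
      "appendage_side": "left",
      "locule_count": 3,
      "organ_states": [
        {
          "identity": "fertile_stamen",
          "position_deg": 225,
          "state": "half_fertile",
          "whorl": "inner_androecium"
        },
        {
          "identity": "stamen_appendage",
          "position_deg": 45,
          "state": "petaloid",
          "whorl": "inner_androecium"
        }
      ],
      "petal_count": 3,
      "sepal_count": 3,
      "style_form": "laminar",
      "symmetry": "asymmetric",
      "theca_count": 1,
      "zygomorphy_axis": null
    }
  },
  "pf_class": "cyme_2f",
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
              "angle_deg": 90,
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
              "angle_deg": 270,
              "fused_with": null,
              "order_index": 2
            },
            "children": [
              {
                "bract": {
                  "angle_deg": 225,
                  "fused_with": null,
                  "order_index": 3
                },
                "children": [],
                "handedness": null,
                "kind": "flower",
                "order": 3,
                "status": "aborted"
              }
            ],
            "handedness": null,
            "kind": "flower",
            "order": 2,
            "status": "mature"
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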