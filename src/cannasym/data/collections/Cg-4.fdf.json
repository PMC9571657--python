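{
  "annotations": {
    "f1": "half-fertile dorsal stamen; asymmetric as in normal flowers",
    "interpretive": "appendage side of the primary flower transcribed as the sinistrorse-consistent side (right)",
    "timing": "deviation attributed to delayed emergence of one secondary branch"
  },
  "figures": [
    "7I",
    "7J",
    "7O"
  ],
  "id": "Cg-4",
  "normal": false,
  "observed": {
    "0": {
      "appendage_side": "right",
      "locule_count": 4,
      "organ_states": [
        {
          "identity": "fertile_stamen",
          "position_deg": 90,
          "state": "half_fertile",
          "whorl": "inner_androecium"
        },
        {
          "identity": "stamen_appendage",
          "position_deg": 270,
          "state": "petaloid",
          "whorl": "inner_androecium"
        }
      ],
      "petal_count": 4,
      "sepal_count": 4,
      "style_form": "filamentous",
      "symmetry": "asymmetric",
      "theca_count": 1,
      "zygomorphy_axis": null
    },
    "0/0": {
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
    },
    "0/1": {
      "appendage_side": "right",
      "locule_count": 3,
      "organ_states": [
        {
          "identity": "fertile_stamen",
          "position_deg": 135,
          "state": "half_fertile",
          "whorl": "inner_androecium"
        },
        {
          "identity": "stamen_appendage",
          "position_deg": 315,
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
  "pf_class": "cyme_3f",
  "rule_exceptions": {},
  "species": "Canna glauca",
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
                  "angle_deg": 135,
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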