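{
  "annotations": {
    "f2": "the single secondary flower sits under the two fused secondary bracts and bears two lateral tertiary bracts; zygomorphic, five petaloid staminodes including two lateral labella; style symmetric, filamentous",
    "interpretive": "the fused secondary-bract pair is encoded as one bract on each member (45/315 degrees), the left member's subtending the secondary flower",
    "pair": "primary flowers asymmetric, mirror images; fertile stamens adjacent to the pair midline"
  },
  "figures": [
    "10",
    "12I"
  ],
  "id": "Ci-7",
  "normal": false,
  "observed": {
    "0": {
      "appendage_side": "right",
      "locule_count": 3,
      "organ_states": [
        {
          "identity": "fertile_stamen",
          "position_deg": 45,
          "state": "half_fertile",
          "whorl": "inner_androecium"
        },
        {
          "identity": "stamen_appendage",
          "position_deg": 225,
          "state": "petaloid",
          "whorl": "inner_androecium"
        }
      ],
      "petal_count": null,
      "sepal_count": null,
      "style_form": "laminar",
      "symmetry": "asymmetric",
      "theca_count": 1,
      "zygomorphy_axis": null
    },
    "0/0": {
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
          "identity": "labellum",
          "position_deg": 120,
          "state": "petaloid",
          "whorl": "inner_androecium"
        },
        {
          "identity": "labellum",
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
    },
    "1": {
      "appendage_side": "left",
      "locule_count": 3,
      "organ_states": [
        {
          "identity": "fertile_stamen",
          "position_deg": 315,
          "state": "half_fertile",
          "whorl": "inner_androecium"
        },
        {
          "identity": "stamen_appendage",
          "position_deg": 135,
          "state": "petaloid",
          "whorl": "inner_androecium"
        }
      ],
      "petal_count": null,
      "sepal_count": null,
      "style_form": "laminar",
      "symmetry": "asymmetric",
      "theca_count": 1,
      "zygomorphy_axis": null
    }
  },
  "pf_class": "thyrse_3f",
  "rule_exceptions": {},
  "species": "Canna indica",
  "topology": {
    "bract": null,
    "children": [
      {
        "bract": {
          "angle_deg": 180,
          "fused_with": "1",
          "order_index": 1
        },
        "children": [
          {
            "bract": {
              "angle_deg": 45,
              "fused_with": "1/0",
              "order_index": 2
            },
            "children": [
              {
                "bract": {
                  "angle_deg": 90,
                  "fused_with": null,
                  "order_index": 3
                },
                "children": [],
                "handedness": null,
                "kind": "flower",
                "order": 3,
                "status": "aborted"
              },
              {
                "bract": {
                  "angle_deg": 270,
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
      },
      {
        "bract": {
          "angle_deg": 180,
          "fused_with": "0",
          "order_index": 1
        },
        "children": [
          {
            "bract": {
              "angle_deg": 315,
              "fused_with": "0/0",
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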