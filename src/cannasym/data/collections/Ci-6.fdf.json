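{
  "annotations": {
    "complex": "conjoined flower pair under two fused primary bracts; the two adaxial petals fused; seven petaloid staminodes of which two are labella; two trilocular ovaries fused, styles separate and laminar",
    "interpretive": "secondary bracts transcribed at the midline-ward diagonal (45/315 degrees in the member frames, where 0 points at the pair midline)",
    "shared_petal_count": 7,
    "shared_sepal_count": 4,
    "stamens": "anthers (one theca each) on the abaxial side of the floral pair, petaloid appendages on the adaxial side relative to the main axis \u2014 i.e. thecae proximal and appendages distal to the fused secondary bracts"
  },
  "figures": [
    "9",
    "12H"
  ],
  "id": "Ci-6",
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
  "pf_class": "thyrse_2f",
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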