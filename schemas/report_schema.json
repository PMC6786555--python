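{
  "$defs": {
    "ConcordanceBlock": {
      "properties": {
        "platform": {
          "title": "Platform",
          "type": "string"
        },
        "mean_within_donor_correlation": {
          "title": "Mean Within Donor Correlation",
          "type": "number"
        },
        "mean_across_donor_correlation": {
          "title": "Mean Across Donor Correlation",
          "type": "number"
        },
        "sn_ratio": {
          "title": "Sn Ratio",
          "type": "number"
        },
        "n_within_pairs": {
          "minimum": 1,
          "title": "N Within Pairs",
          "type": "integer"
        },
        "n_across_pairs": {
          "minimum": 1,
          "title": "N Across Pairs",
          "type": "integer"
        }
      },
      "required": [
        "platform",
        "mean_within_donor_correlation",
        "mean_across_donor_correlation",
        "sn_ratio",
        "n_within_pairs",
        "n_across_pairs"
      ],
      "title": "ConcordanceBlock",
      "type": "object"
    },
    "EnrichmentEntry": {
      "properties": {
        "set": {
          "title": "Set",
          "type": "string"
        },
        "overlap": {
          "title": "Overlap",
          "type": "integer"
        },
        "selected_size": {
          "title": "Selected Size",
          "type": "integer"
        },
        "set_in_universe": {
          "title": "Set In Universe",
          "type": "integer"
        },
        "universe_size": {
          "title": "Universe Size",
          "type": "integer"
        },
        "p": {
          "title": "P",
          "type": "number"
        },
        "fdr": {
          "title": "Fdr",
          "type": "number"
        }
      },
      "required": [
        "set",
        "overlap",
        "selected_size",
        "set_in_universe",
        "universe_size",
        "p",
        "fdr"
      ],
      "title": "EnrichmentEntry",
      "type": "object"
    },
    "PcaBlock": {
      "properties": {
        "explained_variance_ratio": {
          "items": {
            "type": "number"
          },
          "title": "Explained Variance Ratio",
          "type": "array"
        },
        "n_components": {
          "title": "N Components",
          "type": "integer"
        }
      },
      "required": [
        "explained_variance_ratio",
        "n_components"
      ],
      "title": "PcaBlock",
      "type": "object"
    },
    "PropertyCorrelationEntry": {
      "properties": {
        "measure": {
          "title": "Measure",
          "type": "string"
        },
        "property": {
          "title": "Property",
          "type": "string"
        },
        "r": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "R"
        },
        "p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "P"
        },
        "significant": {
          "title": "Significant",
          "type": "boolean"
        },
        "n": {
          "title": "N",
          "type": "integer"
        }
      },
      "required": [
        "measure",
        "property",
        "r",
        "p",
        "significant",
        "n"
      ],
      "title": "PropertyCorrelationEntry",
      "type": "object"
    },
    "StageLog": {
      "properties": {
        "stage": {
          "title": "Stage",
          "type": "string"
        },
        "seconds": {
          "title": "Seconds",
          "type": "number"
        },
        "details": {
          "additionalProperties": {
            "anyOf": [
              {
                "type": "integer"
              },
              {
                "type": "number"
              },
              {
                "type": "string"
              }
            ]
          },
          "title": "Details",
          "type": "object"
        }
      },
      "required": [
        "stage",
        "seconds"
      ],
      "title": "StageLog",
      "type": "object"
    }
  },
  "description": "Machine-readable summary of one pipeline run.",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "n_samples": {
      "title": "N Samples",
      "type": "integer"
    },
    "n_probes": {
      "title": "N Probes",
      "type": "integer"
    },
    "parameters": {
      "additionalProperties": {
        "anyOf": [
          {
            "type": "number"
          },
          {
            "type": "integer"
          },
          {
            "type": "string"
          },
          {
            "type": "null"
          }
        ]
      },
      "title": "Parameters",
      "type": "object"
    },
    "concordance": {
      "items": {
        "$ref": "#/$defs/ConcordanceBlock"
      },
      "title": "Concordance",
      "type": "array"
    },
    "pca": {
      "anyOf": [
        {
          "$ref": "#/$defs/PcaBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "property_correlations": {
      "additionalProperties": {
        "items": {
          "$ref": "#/$defs/PropertyCorrelationEntry"
        },
        "type": "array"
      },
      "title": "Property Correlations",
      "type": "object"
    },
    "enrichment": {
      "additionalProperties": {
        "items": {
          "$ref": "#/$defs/EnrichmentEntry"
        },
        "type": "array"
      },
      "title": "Enrichment",
      "type": "object"
    },
    "stages": {
      "items": {
        "$ref": "#/$defs/StageLog"
      },
      "title": "Stages",
      "type": "array"
    }
  },
  "required": [
    "seed",
    "n_samples",
    "n_probes",
    "parameters",
    "concordance"
  ],
  "title": "PipelineReport",
  "type": "object"
}
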