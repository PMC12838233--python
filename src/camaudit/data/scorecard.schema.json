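{
  "$defs": {
    "ContextOfUse": {
      "properties": {
        "audience": {
          "default": "",
          "title": "Audience",
          "type": "string"
        },
        "task": {
          "title": "Task",
          "type": "string"
        },
        "model": {
          "default": "",
          "title": "Model",
          "type": "string"
        }
      },
      "required": [
        "task"
      ],
      "title": "ContextOfUse",
      "type": "object"
    },
    "CriterionReport": {
      "description": "One criterion's metrics plus its gate verdict.",
      "properties": {
        "criterion": {
          "title": "Criterion",
          "type": "string"
        },
        "summary": {
          "additionalProperties": true,
          "title": "Summary",
          "type": "object"
        },
        "model_accuracy": {
          "additionalProperties": true,
          "title": "Model Accuracy",
          "type": "object"
        },
        "flags": {
          "items": {
            "type": "string"
          },
          "title": "Flags",
          "type": "array"
        },
        "gate_status": {
          "default": "not_evaluated",
          "enum": [
            "passed",
            "failed",
            "gated",
            "not_evaluated"
          ],
          "title": "Gate Status",
          "type": "string"
        },
        "gate_metric": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gate Metric"
        },
        "gate_value": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gate Value"
        },
        "gate_threshold": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gate Threshold"
        }
      },
      "required": [
        "criterion",
        "summary"
      ],
      "title": "CriterionReport",
      "type": "object"
    },
    "DescriptiveCard": {
      "description": "Descriptive half of the card (method documentation).",
      "properties": {
        "overview": {
          "$ref": "#/$defs/MethodOverview"
        },
        "context_of_use": {
          "$ref": "#/$defs/ContextOfUse"
        },
        "limitations_and_recommendations": {
          "items": {
            "type": "string"
          },
          "title": "Limitations And Recommendations",
          "type": "array"
        },
        "validation_setting": {
          "default": "",
          "title": "Validation Setting",
          "type": "string"
        }
      },
      "required": [
        "overview",
        "context_of_use"
      ],
      "title": "DescriptiveCard",
      "type": "object"
    },
    "MethodOverview": {
      "properties": {
        "name": {
          "title": "Name",
          "type": "string"
        },
        "description": {
          "default": "",
          "title": "Description",
          "type": "string"
        },
        "abbreviation": {
          "default": "",
          "title": "Abbreviation",
          "type": "string"
        },
        "type": {
          "default": "local, post-hoc",
          "title": "Type",
          "type": "string"
        },
        "citation": {
          "default": "",
          "title": "Citation",
          "type": "string"
        },
        "software": {
          "default": "",
          "title": "Software",
          "type": "string"
        }
      },
      "required": [
        "name"
      ],
      "title": "MethodOverview",
      "type": "object"
    },
    "UsefulnessPlaceholder": {
      "description": "Usefulness requires a reader study; the card carries its design only.",
      "properties": {
        "status": {
          "default": "requires human study",
          "title": "Status",
          "type": "string"
        },
        "task": {
          "default": "",
          "title": "Task",
          "type": "string"
        },
        "study_arms": {
          "items": {
            "type": "string"
          },
          "title": "Study Arms",
          "type": "array"
        },
        "endpoints": {
          "items": {
            "type": "string"
          },
          "title": "Endpoints",
          "type": "array"
        }
      },
      "title": "UsefulnessPlaceholder",
      "type": "object"
    }
  },
  "description": "Full two-part card with gating state and provenance stamps.",
  "properties": {
    "descriptive": {
      "$ref": "#/$defs/DescriptiveCard"
    },
    "quantitative": {
      "items": {
        "$ref": "#/$defs/CriterionReport"
      },
      "title": "Quantitative",
      "type": "array"
    },
    "usefulness": {
      "$ref": "#/$defs/UsefulnessPlaceholder"
    },
    "gate_status": {
      "additionalProperties": {
        "enum": [
          "passed",
          "failed",
          "gated",
          "not_evaluated"
        ],
        "type": "string"
      },
      "title": "Gate Status",
      "type": "object"
    },
    "seed": {
      "default": 0,
      "title": "Seed",
      "type": "integer"
    },
    "package_version": {
      "default": "0.1.0",
      "title": "Package Version",
      "type": "string"
    }
  },
  "required": [
    "descriptive",
    "quantitative"
  ],
  "title": "Scorecard",
  "type": "object"
}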