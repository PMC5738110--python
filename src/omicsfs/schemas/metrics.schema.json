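{
  "$defs": {
    "StepRecord": {
      "properties": {
        "cutoff": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cutoff"
        },
        "n_dropped": {
          "title": "N Dropped",
          "type": "integer"
        },
        "n_kept": {
          "title": "N Kept",
          "type": "integer"
        },
        "name": {
          "title": "Name",
          "type": "string"
        }
      },
      "required": [
        "name",
        "n_kept",
        "n_dropped"
      ],
      "title": "StepRecord",
      "type": "object"
    }
  },
  "description": "Serialized outcome of ``run`` or ``evaluate``.",
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "mean": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Mean",
      "type": "object"
    },
    "median_n_features": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Median N Features"
    },
    "mode": {
      "title": "Mode",
      "type": "string"
    },
    "n_features_per_step": {
      "items": {
        "type": "integer"
      },
      "title": "N Features Per Step",
      "type": "array"
    },
    "per_split_metrics": {
      "items": {
        "additionalProperties": {
          "type": "number"
        },
        "type": "object"
      },
      "title": "Per Split Metrics",
      "type": "array"
    },
    "per_split_n_features": {
      "items": {
        "type": "integer"
      },
      "title": "Per Split N Features",
      "type": "array"
    },
    "sd": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Sd",
      "type": "object"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "selected_features": {
      "items": {
        "type": "string"
      },
      "title": "Selected Features",
      "type": "array"
    },
    "steps": {
      "items": {
        "$ref": "#/$defs/StepRecord"
      },
      "title": "Steps",
      "type": "array"
    },
    "task": {
      "title": "Task",
      "type": "string"
    },
    "tool": {
      "default": "omicsfs",
      "title": "Tool",
      "type": "string"
    },
    "training_metrics": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Training Metrics",
      "type": "object"
    }
  },
  "required": [
    "mode",
    "task",
    "seed",
    "steps",
    "n_features_per_step",
    "selected_features"
  ],
  "title": "MetricsReport",
  "type": "object"
}
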