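{
  "description": "Structural schema for the run-all report bundle: dotted key path -> required JSON type.",
  "required": {
    "config_hash": "str",
    "master_seed": "int",
    "n_subjects": "int",
    "spectra": "dict",
    "classification": "dict",
    "classification.full_model": "dict",
    "cfc": "dict",
    "conjunction": "dict",
    "conjunction.significant_cells": "list"
  },
  "per_disorder_required": {
    "classification.<disorder>.cv_mean": "dict",
    "classification.<disorder>.null_mean": "dict",
    "classification.<disorder>.anova_accuracy": "dict"
  }
}
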