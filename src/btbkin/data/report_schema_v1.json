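{
  "schema": "btbkin-report",
  "version": 1,
  "required": ["schema_version", "package", "seed", "sections", "missing"],
  "section_names": ["calibration", "kinetics", "efflux", "vessels", "lesions", "stats"],
  "section_required": {
    "calibration": ["slope", "intercept", "r_squared", "n_points"],
    "kinetics": ["groups", "v0_ml_g", "inhibitor_folds"],
    "efflux": ["line", "compounds"],
    "vessels": ["summary", "comparison"],
    "lesions": ["per_lesion", "correlations"],
    "stats": []
  }
}
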