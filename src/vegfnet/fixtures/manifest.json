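[
  {
    "file": "r2_total_synthetic.csv",
    "name": "r2_total",
    "observable": "R2_total_frac",
    "protocol": "r2_total",
    "normalization": "none",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel r2_total, additive-gaussian sigma=0.04)"
  },
  {
    "file": "r2_total_no_nrp1_synthetic.csv",
    "name": "r2_total_no_nrp1",
    "observable": "R2_total_frac",
    "protocol": "r2_total_no_nrp1",
    "normalization": "none",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel r2_total_no_nrp1, additive-gaussian sigma=0.04)"
  },
  {
    "file": "r2_surface_synthetic.csv",
    "name": "r2_surface",
    "observable": "R2_surf_frac",
    "protocol": "r2_surface",
    "normalization": "none",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel r2_surface, additive-gaussian sigma=0.04)"
  },
  {
    "file": "pr2_synthetic.csv",
    "name": "pr2",
    "observable": "pR2_frac",
    "protocol": "pr2",
    "normalization": "none",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel pr2, additive-gaussian sigma=0.04)"
  },
  {
    "file": "pplcg_synthetic.csv",
    "name": "pplcg",
    "observable": "pPLCg",
    "protocol": "pplcg",
    "normalization": "peak",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel pplcg, additive-gaussian sigma=0.04)"
  },
  {
    "file": "ca_norm_synthetic.csv",
    "name": "ca_norm",
    "observable": "Ca_c",
    "protocol": "ca_norm",
    "normalization": "baseline_peak",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel ca_norm, additive-gaussian sigma=0.04)"
  },
  {
    "file": "ca_raw_synthetic.csv",
    "name": "ca_raw",
    "observable": "Ca_c",
    "protocol": "ca_raw",
    "normalization": "none",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel ca_raw, additive-gaussian sigma=0.04)"
  },
  {
    "file": "perk_synthetic.csv",
    "name": "perk",
    "observable": "pERK",
    "protocol": "perk",
    "normalization": "peak",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel perk, additive-gaussian sigma=0.04)"
  },
  {
    "file": "perk_sphk1_block_synthetic.csv",
    "name": "perk_sphk1_block",
    "observable": "pERK",
    "protocol": "perk_sphk1_block",
    "normalization": "none",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel perk_sphk1_block, additive-gaussian sigma=0.04)"
  },
  {
    "file": "vegf_binding_synthetic.csv",
    "name": "vegf_binding",
    "observable": "VEGF_bound",
    "protocol": "vegf_binding",
    "normalization": "peak",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel vegf_binding, additive-gaussian sigma=0.04)"
  },
  {
    "file": "pr2_dose_synthetic.csv",
    "name": "pr2_dose",
    "observable": "pR2_frac",
    "protocol": "pr2_dose",
    "normalization": "peak",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel pr2_dose, additive-gaussian sigma=0.04)"
  },
  {
    "file": "perk_dose_synthetic.csv",
    "name": "perk_dose",
    "observable": "pERK",
    "protocol": "perk_dose",
    "normalization": "peak",
    "weight": 1.0,
    "source": "synthetic (model-generated, panel perk_dose, additive-gaussian sigma=0.04)"
  }
]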