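{
  "version": "v1-pancreas-sbrt-5fx",
  "comment": "Five-fraction pancreatic SBRT OAR limits: GI hot-spot doses, combined-kidney V12, liver D50, cord V23.",
  "constraints": [
    {"structure": "stomach",  "metric_kind": "D_at_volume_mL",   "threshold": 1,  "comparator": "le", "limit": 33.0},
    {"structure": "stomach",  "metric_kind": "D_at_volume_mL",   "threshold": 3,  "comparator": "le", "limit": 20.0},
    {"structure": "stomach",  "metric_kind": "D_at_volume_mL",   "threshold": 9,  "comparator": "le", "limit": 15.0},
    {"structure": "duodenum", "metric_kind": "D_at_volume_mL",   "threshold": 1,  "comparator": "le", "limit": 33.0},
    {"structure": "duodenum", "metric_kind": "D_at_volume_mL",   "threshold": 3,  "comparator": "le", "limit": 20.0},
    {"structure": "duodenum", "metric_kind": "D_at_volume_mL",   "threshold": 9,  "comparator": "le", "limit": 15.0},
    {"structure": "bowel",    "metric_kind": "D_at_volume_mL",   "threshold": 1,  "comparator": "le", "limit": 33.0},
    {"structure": "bowel",    "metric_kind": "D_at_volume_mL",   "threshold": 3,  "comparator": "le", "limit": 20.0},
    {"structure": "bowel",    "metric_kind": "D_at_volume_mL",   "threshold": 9,  "comparator": "le", "limit": 15.0},
    {"structure": "kidney",   "metric_kind": "V_at_dose_Gy_pct", "threshold": 12, "comparator": "le", "limit": 75.0},
    {"structure": "liver",    "metric_kind": "D_at_volume_pct",  "threshold": 50, "comparator": "le", "limit": 12.0},
    {"structure": "cord",     "metric_kind": "V_at_dose_Gy_mL",  "threshold": 23, "comparator": "lt", "limit": 0.35}
  ]
}
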