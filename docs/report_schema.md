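# Survey report JSON schema

`summarize(...).to_dict()` (written by `analysis/01_reproduce_survey.py` to
`results/survey_summary.json` and by `mtpaconf table1 --out`) is a single
JSON object:

```
{
  "n_moieties": int,                 # records analyzed (58 for the survey)
  "n_structures": int,               # distinct CCDC entries (41)
  "amine_class_counts": {class: int},
  "descriptors": {
    <name>: {                        # theta1, tau_f3, tau_sp, tau_ap,
      "name": str,                   #   tau_h, theta2, tau_ome
      "n_total": int,                # rows considered
      "n_used": int,                 # non-null values
      "mean_all": float|null,        # degrees, on (-180, 180]
      "median_all": float|null,
      "wrap_mode": "none"|"ap_seam", # seam descriptors averaged on (-360, 0]
      # present only for windowed descriptors:
      "window": {"lo": float, "hi": float, "interval": str},
      "windowed_mean": float|null,
      "n_in_window": int,
      "excluded_rows": [int, ...]    # row numbers outside the window
    }
  },
  "histograms": {
    <name>: {
      "bin_width": float,            # degrees (10 by default)
      "bins": [{"gt": float, "le": float, "count": int}, ...],
      "wrap_mode": "none"|"ap_seam"
    }
  },
  "amide_form_tally": {              # "secondary" = from primary amines,
    <group>: {"Z": int, "E": int,    # "tertiary" = from secondary amines,
              "indeterminate": int}  # "other" = remaining classes
  },
  "mosher_rows": [int, ...],         # rows entering the tau_h statistics
  "anti_rows": [int, ...],           # carbonyl/methoxy-anti minor conformers
  "as_printed": {key: number}        # the rounded headline panel
}
```

All angles are degrees in (−180, +180]; row numbers refer to the packaged
table (1–58).
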