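{
  "dialect": {
    "separator": ",",
    "encoding": "utf-8",
    "decimal": ".",
    "header": true,
    "missing_tokens": ["", "N/A", "NA", "NaN", "none", "null", "."]
  },
  "columns": {
    "patient_id": "patient_id",
    "t": "t_days",
    "decision": "decision",
    "koos": "koos",
    "size_mm": "size_mm",
    "srt": "srt",
    "sds": "sds",
    "mdl": "mdl",
    "mdr": "mdr",
    "pta_vs_0.25": "pta_vs_0.25",
    "pta_vs_0.5": "pta_vs_0.5",
    "pta_vs_1": "pta_vs_1",
    "pta_vs_2": "pta_vs_2",
    "pta_vs_3": "pta_vs_3",
    "pta_vs_4": "pta_vs_4",
    "pta_vs_6": "pta_vs_6",
    "pta_vs_8": "pta_vs_8",
    "pta_h_0.25": "pta_h_0.25",
    "pta_h_0.5": "pta_h_0.5",
    "pta_h_1": "pta_h_1",
    "pta_h_2": "pta_h_2",
    "pta_h_3": "pta_h_3",
    "pta_h_4": "pta_h_4",
    "pta_h_6": "pta_h_6",
    "pta_h_8": "pta_h_8"
  },
  "notes": {
    "t": "days since the patient's first checkup",
    "pta_*": "pure-tone threshold, dB HL, frequency suffix in kHz",
    "srt": "speech reception threshold, dB; values >= ceiling (default 110) are flagged as audiometer ceiling, not missing",
    "decision": "WaS or Active; Active may occur only at a patient's last checkup"
  }
}
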