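{
  "cartridge_tiff": {
    "container": "multi-page TIFF, one page per (frame_index, channel)",
    "page_tag": "ImageDescription, JSON object",
    "tag_keys": {
      "channel_name": "one of DAPI, CK, CD45, MARKER1, MARKER2",
      "frame_index": "integer >= 0; every frame must carry DAPI, CK and CD45 pages",
      "pixel_size_um": "micrometres per pixel edge; default 0.64 when absent",
      "sample_id": "free text patient/sample identifier"
    }
  },
  "feature_table_csv": {
    "row": "one detected event",
    "columns": [
      "event_id", "frame_index", "centroid_y", "centroid_x",
      "dapi_mean", "dapi_max", "dapi_size", "dapi_eccentricity", "dapi_perimeter", "dapi_perimeter_to_area",
      "ck_mean", "ck_max", "ck_size", "ck_eccentricity", "ck_perimeter", "ck_perimeter_to_area",
      "cd45_mean", "cd45_max", "cd45_size", "cd45_eccentricity", "cd45_perimeter", "cd45_perimeter_to_area",
      "marker1_mean", "marker2_mean", "ck_dapi_overlay", "cd45_dapi_overlay"
    ],
    "units": {
      "*_mean / *_max": "AU (raw stored intensity)",
      "*_size": "um^2",
      "*_perimeter": "um",
      "*_perimeter_to_area": "1/um",
      "*_eccentricity": "dimensionless, 0 = circle",
      "ck_dapi_overlay / cd45_dapi_overlay": "area fraction in [0, 1]"
    },
    "gate_feature_names": {
      "cd45_mean": "Mean intensity CD45",
      "cd45_max": "Max intensity CD45",
      "dapi_mean": "Mean intensity DAPI",
      "ck_mean": "Mean intensity CK",
      "ck_max": "Max intensity CK",
      "ck_size": "CK size",
      "ck_eccentricity": "Eccentricity CK",
      "ck_perimeter": "Perimeter CK",
      "ck_perimeter_to_area": "Perimeter to area CK",
      "ck_dapi_overlay": "CK overlay with DAPI",
      "marker1_mean": "Mean intensity marker 1",
      "marker2_mean": "Mean intensity marker 2",
      "cd45_dapi_overlay": "CD45 overlay with DAPI",
      "cd45_size": "CD45 size"
    }
  },
  "cohort_table_csv": {
    "row": "one patient",
    "columns": {
      "patient_id": "unique text identifier",
      "sex": "F | M",
      "ras_status": "wild-type | mutated",
      "sidedness": "left | right | rectum",
      "grade": "G1 | G2 | G3",
      "nodes": "N0 | N1 | N2",
      "therapy_line": "1 | 2 | 3 | 4",
      "ecog": "0 | 1 | 2",
      "metastatic_sites": "semicolon-joined subset of liver;lung;peritoneum;bone",
      "ctc_manual": "integer >= 0",
      "ctc_auto": "integer >= 0",
      "chc_manual": "integer >= 0",
      "chc_auto": "integer >= 0",
      "os_months": "overall survival, months > 0",
      "os_event": "1 = death observed, 0 = censored",
      "pfs_months": "progression-free survival, months > 0",
      "pfs_event": "1 = progression observed, 0 = censored"
    },
    "missing_values": "empty fields, never sentinels"
  },
  "gate_config_json": {
    "shape": "{\"CTC\": [gate, ...], \"CHC\": [gate, ...]}",
    "gate": "{\"feature\": <gate_feature_name key>, \"comparator\": one of <=, <, >=, >, \"threshold\": number}"
  }
}
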