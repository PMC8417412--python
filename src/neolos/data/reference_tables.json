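{
  "description": "Published summary-table counts for the neonatal late-onset-sepsis rule-out analysis. Exposure counts are reconstructed from the printed per-group frequencies of the source study's marker table (development cohort: 33 culture-confirmed sepsis cases, 72 controls) and performance table (development and temporal validation cohorts). 'printed' blocks carry the values as published; 'discrepant' lists cells whose printed value is inconsistent with the printed counts and is asserted as such, never reconciled.",
  "development": {"n_cases": 33, "n_controls": 72},
  "validation": {"n_cases": 20, "n_controls": 40},
  "health_score_24h": {
    "levels": ["healthy", "equivocal", "sick"],
    "cases": [2, 17, 14],
    "controls": [49, 21, 2],
    "printed_or": {"equivocal": 19.8, "sick": 171.5},
    "printed_ci": {"equivocal": [4.2, 93.6], "sick": [22.1, 1330.5]}
  },
  "marker_table": [
    {"marker": "nlr_high", "cases_exposed": 33, "controls_exposed": 17,
     "printed": {"or": 212.5, "ci": [12.4, 3650.1]}, "discrepant": []},
    {"marker": "crp_high", "cases_exposed": 30, "controls_exposed": 10,
     "printed": {"or": 62.0, "ci": [15.9, 242.0]}, "discrepant": []},
    {"marker": "crp_or_nlr", "cases_exposed": 33, "controls_exposed": 18,
     "printed": {"or": 197.4, "ci": [11.5, 3384.3]}, "discrepant": []},
    {"marker": "thrombocytopenia", "cases_exposed": 17, "controls_exposed": 4,
     "printed": {"or": 17.8, "ci": [5.2, 60.2]}, "discrepant": ["or", "ci_low", "ci_high"]},
    {"marker": "central_line", "cases_exposed": 16, "controls_exposed": 12,
     "printed": {"or": 4.7, "ci": [1.8, 11.8]}, "discrepant": []},
    {"marker": "parenteral_nutrition", "cases_exposed": 28, "controls_exposed": 19,
     "printed": {"or": 15.6, "ci": [5.3, 46.3]}, "discrepant": []},
    {"marker": "tachycardia", "cases_exposed": 27, "controls_exposed": 61,
     "printed": {"or": 0.7, "ci": [0.2, 21.0], "controls_pct": 87.1},
     "discrepant": ["or", "ci_low", "ci_high", "controls_pct"]},
    {"marker": "abnormal_temperature", "cases_exposed": 10, "controls_exposed": 20,
     "printed": {"or": 1.1, "ci": [0.5, 2.8]}, "discrepant": []},
    {"marker": "hyperglycemia", "cases_exposed": 22, "controls_exposed": 23,
     "printed": {"or": 4.3, "ci": [1.7, 10.2]}, "discrepant": []},
    {"marker": "abnormal_wbc", "cases_exposed": 14, "controls_exposed": 13,
     "printed": {"or": 3.3, "ci": [1.3, 8.3]}, "discrepant": []},
    {"marker": "abnormal_neutrophils", "cases_exposed": 30, "controls_exposed": 29,
     "printed": {"or": 14.8, "ci": [4.1, 53.2]}, "discrepant": []},
    {"marker": "lymphopenia", "cases_exposed": 22, "controls_exposed": 6,
     "printed": {"or": 22.0, "ci": [7.3, 66.5]}, "discrepant": []}
  ],
  "performance": {
    "development": [
      {"predictor": "decision_tree", "tp": 33, "fp": 18, "tn": 54, "fn": 0,
       "printed": {"auc": 0.94, "sensitivity": 100.0, "specificity": 75.0, "ppv": 64.7, "npv": 100.0},
       "discrepant": [], "auc_from_nodes": true},
      {"predictor": "culture_positive_24h", "tp": 12, "fp": 0, "tn": 72, "fn": 21,
       "printed": {"auc": 0.68, "sensitivity": 36.4, "specificity": 100.0, "ppv": 100.0, "npv": 77.4},
       "discrepant": []},
      {"predictor": "sick_appearing", "tp": 14, "fp": 2, "tn": 70, "fn": 19,
       "printed": {"auc": 0.70, "sensitivity": 42.4, "specificity": 97.2, "ppv": 87.5, "npv": 78.7},
       "discrepant": []},
      {"predictor": "nlr_high", "tp": 33, "fp": 17, "tn": 55, "fn": 0,
       "printed": {"auc": 0.88, "sensitivity": 100.0, "specificity": 76.4, "ppv": 66.0, "npv": 100.0},
       "discrepant": []},
      {"predictor": "crp_high", "tp": 30, "fp": 10, "tn": 62, "fn": 3,
       "printed": {"auc": 0.89, "sensitivity": 90.9, "specificity": 86.1, "ppv": 75.0, "npv": 95.4},
       "discrepant": []},
      {"predictor": "crp_or_nlr", "tp": 33, "fp": 18, "tn": 54, "fn": 0,
       "printed": {"auc": 0.86, "sensitivity": 100.0, "specificity": 75.0, "ppv": 64.7, "npv": 100.0},
       "discrepant": ["auc"]},
      {"predictor": "abnormal_neutrophils", "tp": 30, "fp": 29, "tn": 43, "fn": 3,
       "printed": {"auc": 0.75, "sensitivity": 90.9, "specificity": 59.2, "ppv": 50.9, "npv": 93.5},
       "discrepant": ["specificity"]}
    ],
    "validation": [
      {"predictor": "decision_tree", "tp": 20, "fp": 19, "tn": 21, "fn": 0,
       "printed": {"auc": 0.92, "sensitivity": 100.0, "specificity": 52.5, "ppv": 52.3, "npv": 100.0},
       "discrepant": ["ppv"], "auc_not_recomputable": true},
      {"predictor": "culture_positive_24h", "tp": 9, "fp": 0, "tn": 40, "fn": 11,
       "printed": {"auc": 0.73, "sensitivity": 45.0, "specificity": 100.0, "ppv": 100.0, "npv": 78.4},
       "discrepant": []},
      {"predictor": "sick_appearing", "tp": 13, "fp": 6, "tn": 34, "fn": 7,
       "printed": {"auc": 0.75, "sensitivity": 65.0, "specificity": 85.4, "ppv": 68.4, "npv": 83.3},
       "discrepant": ["specificity", "npv"]},
      {"predictor": "nlr_high", "tp": 18, "fp": 12, "tn": 28, "fn": 2,
       "printed": {"auc": 0.80, "sensitivity": 90.0, "specificity": 70.0, "ppv": 60.0, "npv": 93.3},
       "discrepant": []},
      {"predictor": "crp_high", "tp": 19, "fp": 11, "tn": 29, "fn": 1,
       "printed": {"auc": 0.84, "sensitivity": 95.0, "specificity": 72.5, "ppv": 63.3, "npv": 96.7},
       "discrepant": []},
      {"predictor": "crp_or_nlr", "tp": 19, "fp": 19, "tn": 21, "fn": 1,
       "printed": {"auc": 0.74, "sensitivity": 95.0, "specificity": 52.5, "ppv": 50.0, "npv": 95.5},
       "discrepant": []},
      {"predictor": "abnormal_neutrophils", "tp": 18, "fp": 16, "tn": 24, "fn": 2,
       "printed": {"auc": 0.75, "sensitivity": 90.0, "specificity": 60.0, "ppv": 52.9, "npv": 92.3},
       "discrepant": []}
    ]
  },
  "tree_nodes_development": {
    "node2": [21, 2],
    "node3": [12, 16],
    "node4": [0, 54]
  },
  "culture": {
    "positive_at_24h": 21,
    "total_cases": 53,
    "printed_pct": 39.6,
    "ttp_median_h": 25.9,
    "ttp_iqr_h": [18.7, 37.3]
  }
}
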