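{
 "schema_version": 1,
 "name": "int_score",
 "intercept": 1.55460,
 "link": "linear",
 "standardization": null,
 "terms": [
  {"slot": "age", "feature": "age", "coefficient": -0.06206, "standardize": false},
  {"slot": "TBRmean", "feature": "TBRmean", "coefficient": 0.11767, "standardize": false},
  {"slot": "TBRmax", "feature": "TBRmax", "coefficient": 1.17543, "standardize": false},
  {"slot": "ClusterProminence_AllDirection_offset4_SD", "feature": "ClusterProminence_AllDirection_offset4_SD", "coefficient": 0.13864, "standardize": true},
  {"slot": "ClusterShade_angle135_offset7", "feature": "ClusterShade_angle135_offset7", "coefficient": -0.24507, "standardize": true},
  {"slot": "InverseDifferenceMoment_AllDirection_offset4_SD", "feature": "InverseDifferenceMoment_AllDirection_offset4_SD", "coefficient": -0.19557, "standardize": true},
  {"slot": "InverseDifferenceMoment_AllDirection_offset7_SD", "feature": "InverseDifferenceMoment_AllDirection_offset7_SD", "coefficient": -0.18425, "standardize": true},
  {"slot": "InverseDifferenceMoment_angle135_offset4", "feature": "InverseDifferenceMoment_angle135_offset4", "coefficient": -0.11953, "standardize": true},
  {"slot": "ShortRunEmphasis_AllDirection_offset4_SD", "feature": "ShortRunEmphasis_AllDirection_offset4_SD", "coefficient": -0.16515, "standardize": true},
  {"slot": "ClusterProminence_angle45_offset7", "feature": "ClusterProminence_angle45_offset7", "coefficient": -0.01222, "standardize": true},
  {"slot": "HaralickCorrelation_AllDirection_offset7_SD", "feature": "HaralickCorrelation_AllDirection_offset7_SD", "coefficient": -0.29295, "standardize": true},
  {"slot": "ShortRunHighGreyLevelEmphasis_AllDirection_offset1_SD", "feature": "ShortRunHighGreyLevelEmphasis_AllDirection_offset1_SD", "coefficient": 0.20089, "standardize": true},
  {"slot": "Quantile0.025", "feature": "Quantile0.025", "coefficient": 0.03032, "standardize": true},
  {"slot": "Correlation_angle45_offset7", "feature": "Correlation_angle45_offset7", "coefficient": 0.12080, "standardize": true},
  {"slot": "ShortRunHighGreyLevelEmphasis_AllDirection_offset4_SD", "feature": "ShortRunHighGreyLevelEmphasis_AllDirection_offset4_SD", "coefficient": 0.02933, "standardize": true}
 ]
}
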