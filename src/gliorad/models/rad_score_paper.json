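{
 "schema_version": 1,
 "name": "rad_score",
 "intercept": -1.161464,
 "link": "linear",
 "standardization": null,
 "terms": [
  {"slot": "Quantile0.025", "feature": "Quantile0.025", "coefficient": -0.111113, "standardize": true},
  {"slot": "RMS", "feature": "RMS", "coefficient": -0.187241, "standardize": true},
  {"slot": "ClusterProminence_AllDirection_offset4_SD", "feature": "ClusterProminence_AllDirection_offset4_SD", "coefficient": -0.154078, "standardize": true},
  {"slot": "ClusterShade_angle0_offset7", "feature": "ClusterShade_angle0_offset7", "coefficient": 0.007201, "standardize": true},
  {"slot": "ClusterShade_angle135_offset7", "feature": "ClusterShade_angle135_offset7", "coefficient": 0.266849, "standardize": true},
  {"slot": "Correlation_AllDirection_offset4_SD", "feature": "Correlation_AllDirection_offset4_SD", "coefficient": 0.202809, "standardize": true},
  {"slot": "Correlation_angle135_offset4", "feature": "Correlation_angle135_offset4", "coefficient": 0.150674, "standardize": true},
  {"slot": "Correlation_angle45_offset7", "feature": "Correlation_angle45_offset7", "coefficient": -0.119975, "standardize": true},
  {"slot": "HaralickCorrelation_AllDirection_offset4_SD", "feature": "HaralickCorrelation_AllDirection_offset4_SD", "coefficient": -0.014077, "standardize": true},
  {"slot": "Inertia_AllDirection_offset7_SD", "feature": "Inertia_AllDirection_offset7_SD", "coefficient": 0.137885, "standardize": true},
  {"slot": "LongRunHighGreyLevelEmphasis_angle135_offset7", "feature": "LongRunHighGreyLevelEmphasis_angle135_offset7", "coefficient": -0.048716, "standardize": true},
  {"slot": "ShortRunLowGreyLevelEmphasis_angle90_offset7", "feature": "ShortRunLowGreyLevelEmphasis_angle90_offset7", "coefficient": 0.222189, "standardize": true},
  {"slot": "RelativeDeviation", "feature": "RelativeDeviation", "coefficient": -0.025067, "standardize": true},
  {"slot": "stdDeviation", "feature": "stdDeviation", "coefficient": -0.254328, "standardize": true},
  {"slot": "GLCMEnergy_angle45_offset7", "feature": "GLCMEnergy_angle45_offset7", "coefficient": 0.102539, "standardize": true},
  {"slot": "HaralickCorrelation_AllDirection_offset1_SD", "feature": "HaralickCorrelation_AllDirection_offset1_SD", "coefficient": 0.014467, "standardize": true},
  {"slot": "HaralickCorrelation_AllDirection_offset7_SD#1", "feature": "HaralickCorrelation_AllDirection_offset7_SD", "coefficient": 0.111329, "standardize": true},
  {"slot": "Sphericity", "feature": "Sphericity", "coefficient": -0.112513, "standardize": true},
  {"slot": "Correlation_angle135_offset7", "feature": "Correlation_angle135_offset7", "coefficient": -0.211177, "standardize": true},
  {"slot": "HaralickCorrelation_AllDirection_offset7_SD#2", "feature": "HaralickCorrelation_AllDirection_offset7_SD", "coefficient": 0.074150, "standardize": true}
 ]
}
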