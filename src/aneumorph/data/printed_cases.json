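{
 "case1_left": {
  "Hmax": 5.311, "H": 5.138, "Dmiddle": 6.649, "Dneck": 6.589, "Dvessel": 3.76,
  "V": 140.293, "S": 108.671, "thetaF": 111.71, "thetaA": 82.4,
  "AR": 0.78, "SR": 1.413, "UI": 0.017, "EI": 0.044, "NSI": 0.046,
  "NWSS": 0.504, "OSI": 0.0073, "RRT": 0.405,
  "RRS_M": 0.1499, "RRS_H": 0.3758, "RRS_C": 0.215,
  "ruptured": false
 },
 "case1_right": {
  "Hmax": 7.578, "H": 6.865, "Dmiddle": 9.143, "Dneck": 7.446, "Dvessel": 3.025,
  "V": 333.099, "S": 206.884, "thetaF": 132.38, "thetaA": 89.36,
  "AR": 0.922, "SR": 2.505, "UI": 0.044, "EI": 0.097, "NSI": 0.108,
  "NWSS": 0.549, "OSI": 0.0215, "RRT": 0.387,
  "RRS_M": 0.4055, "RRS_H": 0.8677, "RRS_C": 0.812,
  "ruptured": true
 },
 "case2_2019": {
  "Hmax": 2.968, "H": 2.145, "Dmiddle": 4.944, "Dneck": 4.981, "Dvessel": 4.295,
  "V": 27.768, "S": 35.333, "thetaF": null, "thetaA": null,
  "AR": 0.431, "SR": 0.691, "UI": 0.018, "EI": 0.001, "NSI": 0.004,
  "NWSS": 0.958, "OSI": 0.0049, "RRT": 0.312,
  "RRS_M": 0.0673, "RRS_H": 0.076, "RRS_C": 0.0399,
  "ruptured": false
 },
 "case2_2021": {
  "Hmax": 4.905, "H": 4.032, "Dmiddle": 5.194, "Dneck": 5.246, "Dvessel": 3.727,
  "V": 48.09, "S": 58.129, "thetaF": 153.45, "thetaA": 125.42,
  "AR": 0.769, "SR": 1.316, "UI": 0.131, "EI": 0.094, "NSI": 0.127,
  "NWSS": 0.487, "OSI": 0.0157, "RRT": 0.808,
  "RRS_M": 0.1352, "RRS_H": 0.742, "RRS_C": 0.4235,
  "ruptured": true
 }
}
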