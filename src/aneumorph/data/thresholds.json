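{
 "thetaF": {"direction": "greater", "cutoff": 118.25},
 "thetaA": {"direction": "greater", "cutoff": 96.1},
 "AR": {"direction": "greater", "cutoff": 1.6},
 "SR": {"direction": "greater", "cutoff": 1.75},
 "UI": {"direction": "greater", "cutoff": 0.09},
 "EI": {"direction": "greater", "cutoff": 0.13},
 "NSI": {"direction": "greater", "cutoff": 0.16},
 "NWSS": {"direction": "less", "cutoff": 0.39},
 "OSI": {"direction": "greater", "cutoff": 0.0036},
 "RRT": {"direction": "greater", "cutoff": 2.7},
 "RRS_M": {"direction": "greater", "cutoff": 0.30},
 "RRS_H": {"direction": "greater", "cutoff": 0.30},
 "RRS_C": {"direction": "greater", "cutoff": 0.30}
}
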