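{
 "D": 0.1,
 "K1": 3.43325195708591,
 "K21": 0.8098527160639127,
 "K22": 0.0769,
 "S": 10.0,
 "Y1": 0.4187556923076923,
 "Y21": 0.07432913538461537,
 "Y22": 1.21875,
 "d1": 1.463885511111111,
 "d2": 1.5616666666666665,
 "dt_dilution": 10.0,
 "mu1": 2.916200273504274,
 "mu21": 2.3024572649572645,
 "mu22": 10.259427749638514,
 "p": 0.0913450453016493,
 "q": 0.566153846153846
}
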