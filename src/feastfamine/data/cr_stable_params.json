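{
 "D": 0.1,
 "K1": 3.43325195708591,
 "K21": 0.8098527160639127,
 "K22": 0.0769,
 "S": 10.0,
 "Y1": 0.4187556923076923,
 "Y21": 0.07432913538461537,
 "Y22": 1.21875,
 "d1": 0.29277710222222225,
 "d2": 0.31233333333333335,
 "dt_dilution": 10.0,
 "mu1": 0.5832400547008548,
 "mu21": 0.46049145299145294,
 "mu22": 2.051885549927703,
 "p": 0.018269009060329862,
 "q": 0.566153846153846
}
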