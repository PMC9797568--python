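parameter,control,treated
mu_batch,0.38,0.37
residual_glucose,0.69,0.69
q_glucose,-5.80,-7.34
q_co2,9.82,11.04
q_ethanol,8.66,13.27
q_glycerol,1.04,0.84
q_lactate,0.08,0.06
q_pyruvate,0.02,0.03
X,2.64,2.14
Y_XS,0.13,0.09
Y_EthS,0.38,0.46
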