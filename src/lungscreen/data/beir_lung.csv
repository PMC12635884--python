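# Excess-risk coefficients for radiation-induced lung cancer in the style
# of the BEIR VII preferred models. beta: ERR per Sv (relative) or EAR per
# 10^4 person-year-Sv (absolute) at exposure age 30+ and attained age 60;
# gamma: per-decade exposure-age modifier (exposure ages capped at 30);
# eta: power of attained age / 60.
model,sex,beta,gamma,eta
err,male,0.32,-0.30,-1.4
err,female,1.40,-0.30,-1.4
ear,male,2.3,-0.41,5.2
ear,female,3.4,-0.41,5.2
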