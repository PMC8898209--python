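{"seed0":{"loglik":-55.7338241775,"sigma2_rep":3.74381991812,"sigma2_block":1.98222191913,"sigma2_e":1.73475565325},"seed1":{"loglik":-50.8455100426,"sigma2_rep":1.06947842291,"sigma2_block":3.6374080489,"sigma2_e":0.761002288429},"seed2":{"loglik":-55.5599200056,"sigma2_rep":1.40092133525,"sigma2_block":2.72236390341,"sigma2_e":1.70869838778},"seed3":{"loglik":-52.7230323417,"sigma2_rep":0,"sigma2_block":1.39220447849,"sigma2_e":1.77852879797},"seed4":{"loglik":-55.585735445,"sigma2_rep":0.274175898997,"sigma2_block":7.7169863955,"sigma2_e":0.942845202563},"seed5":{"loglik":-55.5129217721,"sigma2_rep":6.1707021541,"sigma2_block":3.02275441701,"sigma2_e":1.37737037703},"seed6":{"loglik":-54.0705324313,"sigma2_rep":2.83153941062,"sigma2_block":2.45088906181,"sigma2_e":1.34153050977},"seed7":{"loglik":-52.7741950116,"sigma2_rep":1.03218321507,"sigma2_block":4.98650824664,"sigma2_e":0.798955456498},"seed8":{"loglik":-54.6290482859,"sigma2_rep":3.05248936773,"sigma2_block":3.09068904217,"sigma2_e":1.2480157745},"seed9":{"loglik":-54.7348521632,"sigma2_rep":2.57864645273,"sigma2_block":5.22155635399,"sigma2_e":0.961549777884}}
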