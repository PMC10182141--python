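# Squid-axon sodium/potassium/leak trio, modern resting convention (-65 mV),
# reference temperature 6.3 C with q10 = 3.
mechanisms:
  na_hh:
    gbar: 0.12
    ion: na
    erev: 50.0
    gates:
      m:
        exponent: 3
        alpha: "0.1*(V+40)/(1-exp(-(V+40)/10))"
        beta: "4*exp(-(V+65)/18)"
        q10: 3.0
        ref_temp: 6.3
      h:
        exponent: 1
        alpha: "0.07*exp(-(V+65)/20)"
        beta: "1/(1+exp(-(V+35)/10))"
        q10: 3.0
        ref_temp: 6.3
  k_hh:
    gbar: 0.036
    ion: k
    erev: -77.0
    gates:
      n:
        exponent: 4
        alpha: "0.01*(V+55)/(1-exp(-(V+55)/10))"
        beta: "0.125*exp(-(V+65)/80)"
        q10: 3.0
        ref_temp: 6.3
  leak:
    gbar: 0.0003
    ion: null
    erev: -54.3
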