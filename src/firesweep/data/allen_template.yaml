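# Schema-complete eleven-mechanism template for perisomatic fast-spiking
# interneuron models.  Kinetics are simplified stand-ins chosen to give
# continuous (Type I) firing onset, narrow spikes and an SK-mediated coupling
# between calcium influx and firing rate; swap in fitted definitions from a
# parameter bundle for quantitative work.  Conductances (gbar, S/cm^2) are
# placeholder defaults, normally overridden by the bundle.
#
# Fast-spiking Na/K kinetics follow the interneuron convention (rates
# accelerated 5x, threshold near -55 mV); HVA/LVA calcium and Kv3-like forms
# follow the standard literature formulations used by perisomatic models.
mechanisms:
  NaV:
    gbar: 0.040
    ion: na
    erev: 53.0
    gates:
      m:
        exponent: 3
        alpha: "0.5*(V+35)/(1-exp(-(V+35)/10))"
        beta: "20*exp(-(V+60)/18)"
      h:
        exponent: 1
        alpha: "0.35*exp(-(V+58)/20)"
        beta: "5/(1+exp(-(V+28)/10))"
  Kd:
    gbar: 0.009
    ion: k
    erev: -90.0
    gates:
      n:
        exponent: 4
        alpha: "0.05*(V+34)/(1-exp(-(V+34)/10))"
        beta: "0.625*exp(-(V+44)/80)"
  Kv3_1:
    gbar: 0.003
    ion: k
    erev: -90.0
    gates:
      m:
        exponent: 1
        inf: "1/(1+exp(-(V-18.7)/9.7))"
        tau: "4/(1+exp(-(V+46.56)/44.14))"
  Kv2like:
    gbar: 0.0005
    ion: k
    erev: -90.0
    gates:
      m:
        exponent: 2
        inf: "1/(1+exp(-(V+10)/9))"
        tau: "1+12/(1+exp((V+20)/15))"
  K_T:
    gbar: 0.0001
    ion: k
    erev: -90.0
    gates:
      m:
        exponent: 4
        inf: "1/(1+exp(-(V+47)/29))"
        tau: "0.34+0.92*exp(-((V+71)/59)**2)"
      h:
        exponent: 1
        inf: "1/(1+exp((V+66)/10))"
        tau: "8+49*exp(-((V+73)/23)**2)"
  Im_v2:
    gbar: 0.00005
    ion: k
    erev: -90.0
    gates:
      m:
        exponent: 1
        inf: "1/(1+exp(-(V+48)/7))"
        tau: "15/(exp((V+53)/18)+exp(-(V+53)/19))+1"
  Ih:
    gbar: 0.00005
    ion: nonspecific
    erev: -45.0
    gates:
      m:
        exponent: 1
        inf: "1/(1+exp((V+80)/8))"
        tau: "50/(exp((V+110)/33)+exp(-(V+110)/33))+5"
  SK:
    gbar: 0.001
    ion: k
    erev: -90.0
    ca_activation:
      ca_half: 0.00043
      hill: 4.8
      tau: 1.0
  Ca_HVA:
    gbar: 0.0003
    ion: ca
    gates:
      m:
        exponent: 2
        alpha: "0.055*(V+27)/(1-exp(-(V+27)/3.8))"
        beta: "0.94*exp(-(V+75)/17)"
      h:
        exponent: 1
        alpha: "0.000457*exp(-(V+13)/50)"
        beta: "0.0065/(1+exp(-(V+15)/28))"
  Ca_LVA:
    gbar: 0.00003
    ion: ca
    gates:
      m:
        exponent: 2
        inf: "1/(1+exp(-(V+40)/6))"
        tau: "(5+20/(1+exp((V+35)/5)))/2.95"
      h:
        exponent: 1
        inf: "1/(1+exp((V+90)/6.4))"
        tau: "(20+50/(1+exp((V+50)/7)))/2.95"
  leak:
    gbar: 0.0003
    ion: null
    erev: -65.0
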