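drug,characterization,channel,ic50_uM,hill,provenance
flecainide,I,I_Na,3.2682776773753615,0.7154641821975768,synthetic reconstruction: Hill pair fitted through published block percentages at 1 and 10 uM
flecainide,I,I_Kr,1.653954597131141,0.805822676981502,synthetic reconstruction: Hill pair fitted through published block percentages at 1 and 10 uM
flecainide,I,I_CaL,26.475504320826523,0.9700367766225567,synthetic reconstruction: Hill pair fitted through published block percentages at 1 and 10 uM
nisoldipine,I,I_CaL,0.010091602662065043,0.7563228128879705,synthetic reconstruction: Hill pair fitted through published block percentages at 0.1 and 1 uM
dofetilide,I,I_Kr,0.004166666666666671,1.0,"synthetic reconstruction: IC50 from a single published block percentage at 0.1 uM, Hill coefficient assumed 1"
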