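treatment,substitution_rate,chem_N,chem_P,chem_K,manure_N,manure_P,manure_K,total_N,total_P,total_K
CK,0.00,187,42.6,62.2,0,0,0,187,42.6,62.2
25%,0.25,140,42.6,62.2,47.0,0.42,1.46,187,43.0,63.7
50%,0.50,93.7,42.6,62.2,93.3,0.83,2.89,187,43.4,65.1
75%,0.75,46.8,42.6,62.2,140,1.25,4.35,187,43.9,66.6
100%,1.00,0,42.6,62.2,187,1.66,5.81,187,44.3,68.0
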