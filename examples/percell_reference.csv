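# Reference per-cell fluorescence values (QSU per 10^6 CFU) for the six
# simulated-freshwater nutrient x DOC conditions; inputs to the
# worked-example fraction table (afom analyze with percell_table).
condition,f_T,f_C,f_Cplus
SFW0,50.2,128.6,462.2
SFW1,152.6,66.8,88.1
SFW2,391.8,346.5,237.0
SFW3,647.7,251.8,465.9
SFW4,1346.3,693.2,623.2
SFW5,229.7,929.6,1069.3
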