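# Read percentages as printed in the survey's results text for taxa it
# discusses explicitly; used by the worked-example report to check that the
# summary stage reproduces them from the raw counts.
library	taxon	reported_pct
apple	Metcalfa pruinosa	64.98
apple	Rhopalosiphum insertum	14.6
apple	Myzus persicae	7.62
apple	Cavariella aegopodii	4.45
apple	Aphis gossypii	3.76
apple	Therioaphis trifolii	1.38
linden	Aphis craccivora	8.66
linden	Issus muscaeformis	6.80
linden	Eucallipterus tiliae	2.77
silver_fir_piedmont	Issus muscaeformis	2.89
eucalyptus_calabria	Cinara cedri	7.3
polyfloral_eastern_europe	Metcalfa pruinosa	99.39
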