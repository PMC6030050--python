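# Per-species Hemiptera read counts for 13 honeys from a published COI
# metabarcoding survey (honeydew and blossom honeys from Italy, Corsica and
# Eastern Europe), with the categorical abundance label printed there.
library	taxon	count	reported_category
oak_honeydew	Metcalfa pruinosa	6982	high
honeydew_trentino	Metcalfa pruinosa	6300	high
honeydew_veneto	Metcalfa pruinosa	4392	high
silver_fir_emilia	Cinara pectinatae	2097	high
silver_fir_emilia	Metcalfa pruinosa	1	low
silver_fir_piedmont	Metcalfa pruinosa	1944	high
silver_fir_piedmont	Cinara pectinatae	1899	high
silver_fir_piedmont	Issus muscaeformis	116	low
silver_fir_piedmont	Cinara terminalis	24	low
silver_fir_piedmont	Aphis cisticola	12	low
silver_fir_piedmont	Schizaphis graminum	5	low
silver_fir_piedmont	Mindarus abietinus	4	low
silver_fir_piedmont	Cinara curvipes	1	low
silver_fir_piedmont	Cinara oregonensis	1	low
silver_fir_piedmont	Kaltenbachiella spinosa	1	low
silver_fir_piedmont	Rhopalosiphum maidis	1	low
chestnut	Metcalfa pruinosa	16572	high
apple	Metcalfa pruinosa	657	high
apple	Rhopalosiphum insertum	148	medium
apple	Myzus persicae	77	medium
apple	Cavariella aegopodii	45	low
apple	Aphis gossypii	38	low
apple	Therioaphis trifolii	14	low
apple	Acyrthosiphon pisum	10	low
apple	Aphis craccivora	10	low
apple	Myzocallis castanicola	6	low
apple	Cinara sp.	2	low
apple	Pleotrichophorus sp.	1	low
apple	Aphis cytisorum	1	low
apple	Schizaphis graminum	1	low
apple	Brachycaudus salicinae	1	low
linden	Metcalfa pruinosa	2026	high
linden	Aphis craccivora	219	medium
linden	Issus muscaeformis	172	medium
linden	Eucallipterus tiliae	70	low
linden	Aphididae spp.	15	low
linden	Thelaxes suberi	13	low
linden	Cinara cedri	10	low
linden	Illinoia liriodendri	2	low
linden	Aphis craccae	2	low
linden	Brachycaudus populi	1	low
acacia	Metcalfa pruinosa	2594	high
acacia	Hyalopterus pruni	56	low
acacia	Aphis gossypii	19	low
acacia	Acyrthosiphon caraganae	10	low
acacia	Chaitophorus leucomelas	6	low
acacia	Dysaphis plantaginea	1	low
eucalyptus_calabria	Metcalfa pruinosa	4127	high
eucalyptus_calabria	Cinara cedri	358	medium
eucalyptus_calabria	Aphis gossypii	172	low
eucalyptus_calabria	Aphis taraxacicola	70	low
eucalyptus_calabria	Cinara tujafilina	70	low
eucalyptus_calabria	Brachycaudus cardui	56	low
eucalyptus_calabria	Aphis spiraecola	34	low
eucalyptus_calabria	Aphis craccivora	9	low
eucalyptus_calabria	Aphis glycines	1	low
eucalyptus_calabria	Brachycaudus persicae	1	low
eucalyptus_calabria	Aphis egomae	1	low
eucalyptus_calabria	Cervaphis rappardi	1	low
eucalyptus_sicily	Metcalfa pruinosa	2849	high
eucalyptus_sicily	Myzus persicae	32	low
eucalyptus_sicily	Acyrthosiphon pisum	18	low
eucalyptus_sicily	Issus muscaeformis	7	low
eucalyptus_sicily	Aphis gossypii	1	low
polyfloral_corsica	Metcalfa pruinosa	8675	high
polyfloral_corsica	Aphis gossypii	145	low
polyfloral_corsica	Aphis taraxacicola	57	low
polyfloral_corsica	Thelaxes suberi	23	low
polyfloral_corsica	Aphis ruborum	10	low
polyfloral_corsica	Issus coleoptratus	4	low
polyfloral_corsica	Dysaphis lappae	3	low
polyfloral_corsica	Aphis spiraecola	2	low
polyfloral_corsica	Acyrthosiphon malvae	2	low
polyfloral_corsica	Myzus persicae	2	low
polyfloral_corsica	Aphis glycines	2	low
polyfloral_corsica	Aphis craccivora	2	low
polyfloral_corsica	Cavariella aegopodii	2	low
polyfloral_corsica	Aulacorthum solani	1	low
polyfloral_corsica	Chaitophorus leucomelas	1	low
polyfloral_corsica	Issus muscaeformis	1	low
polyfloral_corsica	Hoplocallis picta	1	low
polyfloral_eastern_europe	Metcalfa pruinosa	22856	high
polyfloral_eastern_europe	Aulacorthum solani	90	low
polyfloral_eastern_europe	Pemphigus bursarius	46	low
polyfloral_eastern_europe	Eucallipterus tiliae	4	low
polyfloral_eastern_europe	Hyperomyzus carduellinus	1	low
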