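category	maize_control	maize_submergence	maize_drought	teosinte_control	teosinte_submergence	teosinte_drought	teosinte_drought_submergence	teosinte_submergence_drought
raw	16139354	26621448	31642210	20672413	28656756	29063588	17997037	46522229
clean	14897058	24568439	29744161	18955892	26296921	26960313	15760258	41915673
genome-mapped	14870947	24488359	29696341	18927434	26217672	26912777	15727757	41761974
mt	87401	106625	134420	114741	73980	105999	106451	145709
cp	182414	452301	459718	475121	444434	835675	973949	1289213
mRNA	195418	258447	342833	207230	202191	256739	238774	309551
rRNA	288257	601629	778148	687038	591868	588819	1056243	1240514
tRNA	103451	161288	200294	569294	480975	553939	953794	1426872
snRNA	516999	838151	1071157	576299	868349	890657	421404	1220748
snoRNA	105518	168088	228389	141006	174443	190297	111528	256675
lncRNA	258027	416896	519449	362527	530505	528963	231375	719402
repeats	2219656	3623199	4820455	5064798	5305481	5343314	4734879	9267896
miRNA	397473	248193	774680	180091	98923	310478	47836	350678
other-miRNA	24837	21526	39108	6498	5862	7393	6470	13887
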