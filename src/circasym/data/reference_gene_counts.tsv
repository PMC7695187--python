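genome	core_n	strain_specific_n	single_copy_n	paralog_n
tokyovirus	269	35	396	95
melbournevirus	265	6	409	96
cannes8_virus	268	3	407	103
marseillevirus	264	7	402	107
marseillevirus_shanghai	266	3	404	101
noumeavirus	277	16	394	113
kurlavirus	272	12	381	114
port_miou_virus	269	8	383	95
lausannevirus	266	3	375	86
tunisvirus	281	31	385	155
brazilian_marseillevirus	272	13	373	114
golden_marseillevirus	282	76	373	170
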