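name	inchikey	formula	logd_ph7	monoisotopic_mass	detected_median_mass	mass_diff_ppm	reference_rt_min	n_injections	detected_rt_min	delta_rt_pct
Guanylurea	BKMMTJMQCTUHRP-UHFFFAOYSA-N	C2H6N4O	-2.1	102.0542	102.0547	4.9	14.4	5	14.6	1.4
Melamine	JDSHMPZPIAZGSV-UHFFFAOYSA-N	C3H6N6	-2.0	126.0654	126.0655	0.8	7.0	5	6.9	-1.3
1,3-Dimethylimidazolidin-2-one	CYSGHNMQYZDMIA-UHFFFAOYSA-N	C5H10N2O	-0.6	114.0793	114.0795	1.8	5.9	2	5.6	-4.8
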