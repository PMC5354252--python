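# Published population-by-sex cell summaries for the four-population study
# cohort: sample size, mean and SD per trait.  Units: height cm, melanin
# index dimensionless, linear distances mm, areas mm^2.
population	sex	trait	n	mean	sd
W_African	M	height	10	179.89	6.48
W_African	F	height	30	164.68	8.61
E_Asian	M	height	43	173.02	6.79
E_Asian	F	height	84	159.94	6.23
N_European	M	height	91	181.00	7.72
N_European	F	height	145	167.15	6.70
S_Asian	M	height	42	173.91	6.13
S_Asian	F	height	31	157.74	6.72
W_African	M	melanin_index	6	59.23	9.68
W_African	F	melanin_index	28	60.27	11.34
E_Asian	M	melanin_index	33	31.42	2.94
E_Asian	F	melanin_index	74	32.63	2.94
N_European	M	melanin_index	91	26.71	2.68
N_European	F	melanin_index	144	28.19	2.60
S_Asian	M	melanin_index	35	38.50	5.82
S_Asian	F	melanin_index	26	39.89	4.72
W_African	M	nares_width	10	45.36	2.74
W_African	F	nares_width	30	39.50	2.95
E_Asian	M	nares_width	43	38.55	2.28
E_Asian	F	nares_width	84	34.35	2.02
N_European	M	nares_width	91	34.29	2.42
N_European	F	nares_width	145	30.91	2.07
S_Asian	M	nares_width	42	37.47	2.59
S_Asian	F	nares_width	31	33.20	1.89
W_African	M	alar_base_width	10	45.31	2.61
W_African	F	alar_base_width	30	40.57	2.56
E_Asian	M	alar_base_width	43	39.98	2.31
E_Asian	F	alar_base_width	84	36.60	1.93
N_European	M	alar_base_width	91	35.66	2.53
N_European	F	alar_base_width	145	33.00	1.98
S_Asian	M	alar_base_width	42	37.77	2.57
S_Asian	F	alar_base_width	31	34.33	1.92
W_African	M	nasal_height	10	51.31	2.36
W_African	F	nasal_height	30	49.15	3.04
E_Asian	M	nasal_height	43	52.35	2.52
E_Asian	F	nasal_height	84	48.76	2.03
N_European	M	nasal_height	91	51.59	2.64
N_European	F	nasal_height	145	48.62	2.11
S_Asian	M	nasal_height	42	50.81	2.34
S_Asian	F	nasal_height	31	47.31	2.13
W_African	M	nasal_ridge_length	10	46.31	2.63
W_African	F	nasal_ridge_length	30	43.82	2.76
E_Asian	M	nasal_ridge_length	43	47.14	2.59
E_Asian	F	nasal_ridge_length	84	43.41	2.24
N_European	M	nasal_ridge_length	91	47.82	2.78
N_European	F	nasal_ridge_length	145	44.78	2.37
S_Asian	M	nasal_ridge_length	42	46.59	2.35
S_Asian	F	nasal_ridge_length	31	43.57	2.47
W_African	M	nasal_tip_protrusion	10	15.94	1.44
W_African	F	nasal_tip_protrusion	30	14.43	0.98
E_Asian	M	nasal_tip_protrusion	43	15.81	1.35
E_Asian	F	nasal_tip_protrusion	84	14.47	1.11
N_European	M	nasal_tip_protrusion	91	17.62	1.25
N_European	F	nasal_tip_protrusion	145	16.43	1.02
S_Asian	M	nasal_tip_protrusion	42	16.60	1.23
S_Asian	F	nasal_tip_protrusion	31	15.68	1.26
W_African	M	external_surface_area	10	1782.13	122.92
W_African	F	external_surface_area	30	1477.42	167.39
E_Asian	M	external_surface_area	43	1604.73	154.02
E_Asian	F	external_surface_area	84	1315.35	100.95
N_European	M	external_surface_area	91	1758.72	153.36
N_European	F	external_surface_area	145	1470.61	118.68
S_Asian	M	external_surface_area	42	1719.14	134.48
S_Asian	F	external_surface_area	31	1422.48	122.86
W_African	M	nostril_area	10	70.17	10.41
W_African	F	nostril_area	30	57.18	9.75
E_Asian	M	nostril_area	43	57.59	7.61
E_Asian	F	nostril_area	84	45.40	4.77
N_European	M	nostril_area	91	54.46	5.97
N_European	F	nostril_area	145	45.80	5.13
S_Asian	M	nostril_area	42	60.83	8.87
S_Asian	F	nostril_area	31	48.52	6.48
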