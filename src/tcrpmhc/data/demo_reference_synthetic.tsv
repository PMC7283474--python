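complex_id	crossing_angle	incident_angle	x_pos	y_pos
synthetic_01	32.0	5.0	-2.1	0.4
synthetic_02	45.0	8.0	-1.0	1.2
synthetic_03	61.0	3.0	-3.5	-0.8
synthetic_04	38.0	12.0	0.5	2.0
synthetic_05	52.0	6.0	-2.8	0.9
synthetic_06	29.0	15.0	1.8	-1.1
synthetic_07	70.0	2.0	-4.0	0.2
synthetic_08	41.0	9.0	-0.6	1.5
synthetic_09	55.0	18.0	2.4	-0.5
synthetic_10	36.0	4.0	-1.9	0.7
synthetic_11	48.0	11.0	0.1	-2.2
synthetic_12	63.0	7.0	-3.1	1.0
synthetic_13	33.0	21.0	3.0	0.3
synthetic_14	58.0	1.0	-2.5	-1.4
synthetic_15	44.0	14.0	1.2	0.8
synthetic_16	67.0	10.0	-0.9	-0.2
synthetic_17	39.0	24.0	3.8	1.7
synthetic_18	51.0	5.0	-1.6	-0.9
synthetic_19	30.0	16.0	2.0	0.6
synthetic_20	73.0	8.0	-3.8	-1.6
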