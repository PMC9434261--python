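intermediate	monoq_peak	treatment	fraction	ion_label	expected_mz_printed	observed_mz
UDP-GlcNAc	1	Fos400	C3-C4 F15	(m-1)/1	606.0738	606.0814
UDP-GlcNAc	1	Fos400	C3-C4 F15	(m+Na-1)/1	628.0557	628.0628
UDP-GlcNAc	1	Fos400	C3-C4 F15	(m-2)/2	302.5330	302.5352
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F19	(m-2)/2	374.0621	374.0696
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F20	(m-2)/2	374.0621	374.0698
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F19	(m-1)/1	749.1320	749.1476
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F20	(m-1)/1	749.1320	749.1488
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F19	(m+Na-1)/1	771.1139	771.1294
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F20	(m+Na-1)/1	771.1139	771.1281
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F19	(m+2Na-1)/1	793.0959	793.1107
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F20	(m+2Na-1)/1	793.0959	793.1127
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F19	(m+3Na-1)/1	815.0778	815.0909
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F20	(m+3Na-1)/1	815.0778	815.0963
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F19	(m+Na-2)/2	385.0531	385.0607
UDP-MurNAc-Ala	2	D-cyclo100	C3-C4 F20	(m+Na-2)/2	385.0531	385.0611
UDP-MurNAc-Ala-Glu	3	D-cyclo100	C3-C4 F23	(m-2)/2	438.5833	438.5928
UDP-MurNAc-Ala-Glu	3	D-cyclo100	C3-4 F24-25	(m-2)/2	438.5833	438.5935
UDP-MurNAc-Ala-Glu	3	D-cyclo100	C3-C4 F23	(m+Na-2)/2	449.5744	449.5839
UDP-MurNAc-Ala-Glu	3	D-cyclo100	C3-4 F24-25	(m+Na-2)/2	449.5744	449.5858
UDP-MurNAc-Ala-Glu	3	D-cyclo100	C3-C4 F23	(m+2Na-2)/2	460.5653	460.5750
UDP-MurNAc-Ala-Glu	3	D-cyclo100	C3-4 F24-25	(m+2Na-2)/2	460.5653	460.5716
UDP-MurNAc-Ala-Glu	3	Cb100	C7-C8 F23	(m-2)/2	438.583	438.5916
UDP-MurNAc-Ala-Glu	3	Cb100	C7-C8 F23	(m+Na-2)/2	449.5744	449.5829
UDP-MurNAc-Ala-Glu	3	Cb100	C7-C8 F23	(m+2Na-2)/2	460.5653	460.5743
UDP-MurNAc-Ala-Glu	3	Cb100	C7-C8 F23	(m-3)/3	292.0530	292.0575
UDP-MurNAc-tripeptide-DAP	4	KNOPS	C7-C8 F18-19	(m-2)/2	524.6258	524.6289
UDP-MurNAc-tripeptide-DAP	4	KNOPS	C7-C8 F20	(m-2)/2	524.6258	524.6289
UDP-MurNAc-tripeptide-DAP	4	KNOPS	C7-C8 F20	(m+Na-2)/2	535.6168	535.6196
UDP-MurNAc-tripeptide-DAP	4	KNOPS	C7-C8 F20	(m+2Na-2)/2	546.6077	546.6108
UDP-MurNAc-tripeptide-DAP	4	KNOPS	C7-C8 F20	(m-3)/3	349.4146	349.4155
UDP-MurNAc-tripeptide-DAP	4	D-cyclo100	C3-C4 F20	(m-2)/2	524.6258	524.6377
UDP-MurNAc-tripeptide-DAP	4	D-cyclo100	C3-C4 F20	(m+Na-2)/2	535.6168	535.6290
UDP-MurNAc-tripeptide-DAP	4	D-cyclo100	C3-C4 F20	(m+2Na-2)/2	546.6077	546.6197
UDP-MurNAc-tripeptide-DAP	4	D-cyclo100	C3-C4 F20	(m+3Na-2)/2	557.5987	557.6108
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F19	(m-2)/2	524.6258	524.6317
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F20	(m-2)/2	524.6258	524.6324
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F19	(m+Na-2)/2	535.6168	535.6230
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F20	(m+Na-2)/2	535.6168	535.6234
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F19	(m+2Na-2)/2	546.6077	546.6139
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F20	(m+2Na-2)/2	546.6077	546.6144
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F20	(m+3Na-2)/2	557.5987	557.6004
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F19	(m-3)/3	349.4146	349.4173
UDP-MurNAc-tripeptide-DAP	4	Cb100	C7-C8 F20	(m-3)/3	349.4146	349.4178
UDP-MurNAc-pentapeptide-DAP	5	KNOPS	C7-C8 F18-19	(m-2)/2	595.6629	595.6646
UDP-MurNAc-pentapeptide-DAP	5	KNOPS	C7-C8 F18-19	(m+Na-2)/2	606.6539	606.6553
UDP-MurNAc-pentapeptide-DAP	5	KNOPS	C7-C8 F18-19	(m-3)/3	396.7726	396.7740
UDP-MurNAc-pentapeptide-DAP	5	Cb100	C7-C8 F19	(m-2)/2	595.6629	595.6693
UDP-MurNAc-pentapeptide-DAP	5	Cb100	C7-C8 F19	(m+Na-2)/2	606.6539	606.6602
UDP-MurNAc-pentapeptide-DAP	5	Cb100	C7-C8 F19	(m+2Na-2)/2	617.6446	617.6509
UDP-MurNAc-pentapeptide-DAP	5	Cb100	C7-C8 F19	(m-3)/3	396.7726	396.7763
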