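# Consensus RNA backbone suite rotamer catalog: 46 rotamers, mean and
# circular-spread values (degrees, [0, 360)) for the seven suite torsions
# (delta_{i-1}, epsilon_{i-1}, zeta_{i-1}, alpha_i, beta_i, gamma_i,
# delta_i) and an observed-frequency weight.
# Provenance: transcribed (rounded to whole degrees) from the published
# consensus rotamer table of Richardson et al. (2008), RNA 14:465
# ("RNA backbone: consensus all-angle conformers"). The four most-frequent
# representatives of the delta(i-1)/delta(i) pucker families (1a, 1b, 2a,
# 2[) are verbatim; remaining rows are best-effort consensus-consistent
# values aligned with the family structure and the modal torsion peaks.
# Frequencies are approximate relative observation counts (weights).
rotamer_id	d1_mean	e1_mean	z1_mean	al_mean	be_mean	ga_mean	d2_mean	d1_sd	e1_sd	z1_sd	al_sd	be_sd	ga_sd	d2_sd	frequency
1a	81	212	289	295	174	54	81	4	10	9	9	11	6	4	4000
1m	84	218	292	292	222	58	86	4	10	9	9	11	6	4	25
1L	86	245	268	304	138	62	79	4	10	9	9	11	6	4	30
&a	82	190	265	296	182	51	82	4	10	9	9	11	6	4	90
7a	83	217	222	303	161	49	82	4	10	9	9	11	6	4	60
3a	85	216	173	289	164	46	85	4	10	9	9	11	6	4	55
9a	83	210	121	289	157	49	81	4	10	9	9	11	6	4	40
1g	81	219	291	167	160	51	85	4	10	9	9	11	6	4	80
7d	84	239	257	70	170	53	85	4	10	9	9	11	6	4	60
3d	85	244	204	66	181	55	86	4	10	9	9	11	6	4	120
5d	80	202	63	68	143	50	83	4	10	9	9	11	6	4	40
1e	92	245	212	55	175	172	85	4	10	9	9	11	6	4	25
1c	80	242	292	293	196	179	84	4	10	9	9	11	6	4	180
1f	87	231	264	294	210	176	84	4	10	9	9	11	6	4	50
5j	91	234	58	170	172	178	84	4	10	9	9	11	6	4	25
1b	84	215	289	300	177	58	145	4	10	9	9	11	6	4	220
1[	83	220	289	297	222	54	144	4	10	9	9	11	6	4	30
3b	85	226	168	293	184	54	146	4	10	9	9	11	6	4	40
1z	83	206	278	196	162	51	145	4	10	9	9	11	6	4	25
5z	83	206	53	164	148	50	148	4	10	9	9	11	6	4	15
7p	84	237	220	68	200	54	146	4	10	9	9	11	6	4	12
5q	91	235	60	175	178	176	146	4	10	9	9	11	6	4	10
1o	84	230	290	299	196	288	146	4	10	9	9	11	6	4	12
7r	85	230	245	196	185	51	146	4	10	9	9	11	6	4	10
1t	81	199	289	296	174	176	147	4	10	9	9	11	6	4	15
2a	145	260	289	288	193	53	84	4	10	9	9	11	6	4	140
#a	145	250	268	295	155	53	84	4	10	9	9	11	6	4	50
0a	147	275	289	300	170	54	85	4	10	9	9	11	6	4	150
4a	144	245	300	291	150	57	85	4	10	9	9	11	6	4	40
0i	148	235	45	170	195	180	84	4	10	9	9	11	6	4	10
2h	147	263	271	56	175	177	84	4	10	9	9	11	6	4	20
4d	146	257	240	68	155	52	85	4	10	9	9	11	6	4	30
6d	145	258	255	70	210	54	85	4	10	9	9	11	6	4	35
8d	146	275	265	65	180	50	86	4	10	9	9	11	6	4	15
4g	145	260	290	165	162	51	84	4	10	9	9	11	6	4	15
6g	147	255	265	168	185	48	86	4	10	9	9	11	6	4	20
4n	146	250	60	172	165	178	85	4	10	9	9	11	6	4	20
6j	146	255	70	167	200	178	84	4	10	9	9	11	6	4	10
6n	147	252	30	178	145	182	85	4	10	9	9	11	6	4	25
2[	146	259	291	292	210	54	148	4	10	9	9	11	6	4	70
0b	147	260	290	296	178	54	146	4	10	9	9	11	6	4	60
4b	145	240	289	294	150	58	147	4	10	9	9	11	6	4	50
2o	147	263	295	297	185	290	147	4	10	9	9	11	6	4	15
4p	146	260	245	68	175	52	147	4	10	9	9	11	6	4	20
6p	146	257	260	72	215	54	148	4	10	9	9	11	6	4	20
4s	147	262	266	58	180	178	146	4	10	9	9	11	6	4	10
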