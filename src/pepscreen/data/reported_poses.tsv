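sequence	target	pose	energy_mean	energy_sd
MWKLPMFGCT	4FYQ	1	-52.98	2.58
WKLPM	4FYQ	1	-45.91	1.77
DLLNIFE	2ONC	1	-41.36	1.47
LMAALNLVG	2ONC	1	-38.08	1.52
HWLNTHAVIE	2ONC	1	-36.91	3.16
TFAFQAE	2ONC	1	-36.46	5.99
QFVTFMK	2ONC	1	-35.22	6.75
QEFAHDFQAY	2ONC	1	-33.71	4.20
LPHPDGDQFG	2ONC	1	-33.24	1.29
GWAPQVLLLS	2ONC	1	-31.93	2.32
LAQNNVMFE	2ONC	1	-30.91	1.43
EMIWDLLVS	2ONC	1	-30.7	4.15
MEMGESP	1O86	1	-60.77	6.10
VEMQDVKYP	1O86	1	-55.91	3.41
MEEVDVAPPQK	1O86	1	-54.94	6.25
ANQPLPDDDDEA	1O86	1	-50.70	10.09
VIPKENN	1O86	1	-50.18	7.84
IDWKETPEPH	1O86	1	-44.58	6.55
FEKGTHIPP	1O86	1	-41.23	1.85
FYQYNPDS	1O86	1	-36.80	0.52
VKVPEPT	1O86	1	-31.71	1.87
PTKGSSVAIFGLGAVGLAAAEGAR	3E7G	1	-50.68	2.3
DSSMAGYMSSKKTMEINPENSIM	3E7G	1	-47.66	1.77
NQKNLHKRYAYQIVLQTREMLR	3E7G	1	-42.12	3.52
DKRIFFTNKSYLPSQTPSGVIR	3E7G	1	-41.85	1.58
DTQPPRLPTKAVRVTAEEVR	3E7G	1	-32.76	1.31
DETPELMPLSHVLATKLGAR	3E7G	1	-32.72	5.92
SAILATPSGERTMTSEQMVY	3E7G	1	-32.46	3.72
CGYSMNSIEGAAVSTIHITPE	3E7G	1	-30.5	0.99
DGPNASYITPAAL	4C12	1	-39.64	0.64
DFGWGNPIFGGILKAISFTSFGVSVKN	4C12	1	-34.96	5.57
DAGASKTYPQQAGTIRKGGHIVIKNRP	4C12	1	-32.89	3.17
DKVCVLSCGISTGLGASLNVAKP	4C12	1	-32.30	2.22
DFLIGNTSTGYCAGGCAAIV	4C12	1	-30.94	2.68
DAGASKTYPQQAGTIRKGGHIVIKNRP	3QDL	1	-32.07	4.96
DHVGFSCSTSGGAASRGILGPFGVIVIA	6EW3	1	-49.54	4.09
DFLIGNTSTGYCAGGCAAIV	6EW3	1	-47.72	1.56
DAGASKTYPQQAGTIRKNGYIVIKGRP	6EW3	1	-45.81	5.54
DKVCVLSCGISTGLGASLNVAKP	6EW3	1	-39.7	2.04
DAGASKTYPQQAGTIRKGGHIVIKNRP	6EW3	1	-30.6	1.28
DHVGFSCSTSGGAASRGILGPFGVIVIA	6FZB	1	-45.95	3.77
DGPNASYITPAAL	6FZB	1	-44.92	1.42
DFLIGNTSTGYCAGGCAAIV	6FZB	1	-33.77	3.73
DKVCVLSCGISTGLGASLNVAKP	6FZB	1	-32.74	5.71
DAGASKTYPQQAGTIRKGGHIVIKNRP	3UDF	1	-32.07	1.49
DKVCVLSCGISTGLGASLNVAKP	3UDF	1	-31.44	2.67
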