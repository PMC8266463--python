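# SYNTHETIC coefficient table fitted to this package's growth simulator; not the originally published Khamis-Roche values. Replace for real-data use.
sex	age	intercept	coef_height	coef_weight	coef_midparent
F	8.0	22.3545	0.7893	0.7037	0.0685
F	8.5	26.8016	0.7291	0.7909	0.0539
F	9.0	26.6235	0.7232	0.7405	0.0482
F	9.5	26.8581	0.6965	0.7169	0.0553
F	10.0	29.315	0.6635	0.7298	0.0472
F	10.5	31.5886	0.6244	0.7366	0.0484
F	11.0	30.805	0.6155	0.7219	0.0459
F	11.5	32.9641	0.5871	0.7225	0.0436
F	12.0	33.5015	0.5731	0.7112	0.0416
F	12.5	33.8383	0.5548	0.7218	0.0456
F	13.0	34.1901	0.5478	0.7049	0.0461
F	13.5	34.3026	0.5515	0.6892	0.041
F	14.0	37.039	0.5196	0.7233	0.0405
F	14.5	38.028	0.503	0.745	0.0403
F	15.0	39.3147	0.5027	0.7362	0.0311
F	15.5	39.3434	0.504	0.7192	0.0314
F	16.0	39.8295	0.5004	0.7233	0.0268
F	16.5	39.1577	0.4967	0.7154	0.0342
F	17.0	38.5387	0.4949	0.7102	0.0385
M	8.0	25.9983	0.8206	0.7832	0.0613
M	8.5	27.0137	0.7784	0.7953	0.0665
M	9.0	28.1714	0.7596	0.7866	0.0562
M	9.5	29.3512	0.7453	0.7791	0.0433
M	10.0	31.82	0.7001	0.7902	0.0462
M	10.5	31.8613	0.676	0.7972	0.0463
M	11.0	31.9628	0.6568	0.7635	0.0523
M	11.5	35.8505	0.6327	0.7692	0.0319
M	12.0	35.6699	0.5987	0.7831	0.0422
M	12.5	36.5895	0.5783	0.7643	0.0425
M	13.0	37.8735	0.5582	0.7568	0.0377
M	13.5	39.1753	0.5571	0.7223	0.025
M	14.0	39.266	0.5332	0.7105	0.0352
M	14.5	43.4955	0.4997	0.7478	0.0237
M	15.0	42.6422	0.4991	0.7284	0.0267
M	15.5	43.2192	0.5017	0.7157	0.0191
M	16.0	44.1733	0.4882	0.7159	0.0214
M	16.5	44.5715	0.4766	0.7191	0.0258
M	17.0	45.8662	0.4568	0.7421	0.0267
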