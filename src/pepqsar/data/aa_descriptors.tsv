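residue	c1	c2	c3	c4	c5	c6	c7	c8	c9	c10	c11	c12	c13	c14	c15	c16	c17	c18
Ala	-1.15	1.12	-1.10	0.06	-0.77	-1.59	-0.56	0.92	0.78	-1.24	0.15	0.21	-0.01	-1.43	-0.89	0.08	0.56	0.51
Arg	2.33	2.47	1.62	3.60	0.73	1.90	-0.38	-0.83	-0.01	1.72	1.18	-2.19	-0.48	1.29	-1.95	-0.46	0.16	-0.76
Asn	-0.32	-0.50	-0.58	0.54	-0.34	-0.15	-0.26	-0.40	-2.42	-0.36	0.36	-0.30	-0.60	-0.38	0.48	0.06	-1.75	-0.20
Asp	-0.75	0.14	-0.67	-0.27	0.69	-0.80	1.88	-1.00	1.08	-0.87	-1.37	-0.37	-0.48	-0.43	1.17	0.78	-1.70	1.22
Cys	-0.72	0.21	-0.89	0.06	-0.71	-0.79	-1.26	0.38	-0.31	-0.76	1.12	1.45	1.04	-1.20	1.16	1.34	1.52	-1.87
Gln	0.31	-0.98	-0.07	0.23	0.24	0.61	-0.38	-0.59	-0.89	0.18	0.56	-0.80	-0.71	0.36	-0.19	-0.09	-1.55	-0.64
Glu	0.32	-0.99	-0.47	0.07	-0.31	0.46	-0.17	-1.51	0.68	0.03	0.43	-0.62	-0.98	0.17	0.09	0.25	-1.92	-0.28
Gly	-1.27	1.39	-1.28	0.24	-1.47	-1.53	-1.83	0.05	1.12	-1.49	1.02	0.68	-0.42	-2.01	-2.20	1.05	0.00	0.07
His	0.30	-1.20	0.02	-0.11	-0.65	0.51	-0.13	-0.04	0.42	0.52	0.38	1.12	-2.42	0.47	0.75	0.23	-0.09	0.26
Ile	-0.64	-0.07	-0.12	-0.58	2.71	-0.68	2.10	0.35	-0.29	-0.27	-2.04	-0.93	0.70	0.37	1.02	-1.54	0.39	0.03
Leu	-0.24	-0.64	0.14	-0.75	1.56	0.22	0.53	-0.17	1.93	-0.02	-0.35	-0.93	1.17	0.38	-0.01	-1.79	0.15	-0.53
Lys	1.27	0.18	0.76	0.60	-0.58	1.24	-0.61	-0.45	0.29	0.90	0.86	-1.16	0.81	0.85	-1.52	-1.12	0.37	-0.35
Met	0.48	-0.78	0.03	0.04	-0.58	0.67	-0.72	-0.30	-1.03	0.30	1.37	0.72	2.37	0.28	0.83	0.96	0.54	-2.25
Phe	0.80	-1.14	1.32	-1.23	-0.60	0.80	-0.17	0.58	0.75	1.03	-0.16	1.20	0.73	1.01	0.21	0.69	0.49	0.31
Pro	-0.84	0.36	-0.67	-0.39	0.33	-0.77	0.34	-0.95	-0.99	-0.77	-0.70	0.06	-0.14	0.59	0.60	0.25	1.36	2.26
Ser	-0.83	0.41	-0.92	0.45	-0.68	-1.05	-1.12	0.83	-0.43	-0.93	0.55	0.34	-0.67	1.16	0.58	0.40	0.10	0.30
Thr	-0.75	0.21	-0.48	-0.05	0.65	-0.59	0.50	-0.03	0.11	-0.71	-0.38	-0.15	-0.04	0.62	0.42	0.89	0.26	0.18
Trp	0.81	-1.52	2.09	-1.15	-0.43	1.05	0.89	3.28	-0.49	2.01	-1.80	1.68	-0.04	1.83	0.27	1.83	0.84	1.29
Tyr	1.71	0.94	1.79	-0.95	-0.91	1.25	0.00	0.39	0.75	1.42	0.06	0.72	-0.38	1.20	0.12	0.69	0.09	0.38
Val	-0.84	0.38	-0.52	-0.41	1.11	-0.76	1.33	-0.49	-1.03	-0.67	-1.23	-0.74	0.54	0.37	1.00	1.43	0.91	0.05
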