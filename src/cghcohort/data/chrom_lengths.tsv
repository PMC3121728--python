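chrom	length_mb
CFA1	125.0
CFA2	88.0
CFA3	95.0
CFA4	91.0
CFA5	91.0
CFA6	80.0
CFA7	83.0
CFA8	77.0
CFA9	64.0
CFA10	72.0
CFA11	77.0
CFA12	75.0
CFA13	66.0
CFA14	63.0
CFA15	67.0
CFA16	59.0
CFA17	67.0
CFA18	53.0
CFA19	56.0
CFA20	61.0
CFA21	54.0
CFA22	64.0
CFA23	55.0
CFA24	51.0
CFA25	54.0
CFA26	42.0
CFA27	49.0
CFA28	44.0
CFA29	44.0
CFA30	43.0
CFA31	42.0
CFA32	41.0
CFA33	34.0
CFA34	47.0
CFA35	30.0
CFA36	33.0
CFA37	33.0
CFA38	26.0
CFAX	127.0
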