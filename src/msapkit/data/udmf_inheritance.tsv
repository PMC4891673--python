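locus	ref_call	variant_call	GS1-GS2	GS2-GS3	GS3-GS4	GS4-GS5
uDMF1	(0, 1)	(1, 1)	86.67 (13/15)	33.33 (5/15)	10.00 (1/10)	30.00 (3/10)
uDMF2	(0, 1)	(1, 1)	60.00 (9/15)	60.00 (9/15)	30.00 (3/10)	40.00 (4/10)
uDMF3	(0, 1)	(1, 1)	60.00 (9/15)	53.33 (8/15)	30.00 (3/10)	20.00 (2/10)
uDMF4	(0, 1)	(1, 1)	20.00 (3/15)	13.33 (2/15)	50.00 (5/10)	20.00 (2/10)
uDMF5	(1, 1)	(0, 1)	93.33 (14/15)	60.00 (9/15)	60.00 (6/10)	60.00 (6/10)
uDMF6	(1, 1)	(0, 1)	93.33 (14/15)	20.00 (3/15)	70.00 (7/10)	80.00 (8/10)
uDMF7	(1, 1)	(0, 1)	60.00 (9/15)	53.33 (8/15)	20.00 (2/10)	30.00 (3/10)
uDMF8	(0, 0)	(1, 0)	0.00 (0/15)	0.00 (0/15)	0.00 (0/10)	0.00 (0/10)
uDMF9	(1, 1)	(0, 1)	100.00	100.00	100.00	100.00
uDMF10	(1, 1)	(1, 0)	100.00	100.00	100.00	100.00
uDMF11	(1, 1)	(0, 1)	100.00	100.00	100.00	100.00
uDMF12	(1, 1)	(0, 1)	100.00	100.00	100.00	100.00
uDMF13	(1, 1)	(0, 1)	100.00	100.00	100.00	100.00
uDMF14	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF15	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF16	(1, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF17	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF18	(0, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF19	(1, 1)	(0, 1)	100.00	100.00	100.00	100.00
uDMF20	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF21	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF22	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF23	(1, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF24	(1, 1)	(0, 1)	100.00	100.00	100.00	100.00
uDMF25	(0, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF26	(1, 0)	(0, 0)	100.00	100.00	100.00	100.00
uDMF27	(1, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF28	(1, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF29	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
uDMF30	(1, 0)	(1, 1)	100.00	100.00	100.00	100.00
uDMF31	(0, 1)	(0, 0)	100.00	100.00	100.00	100.00
uDMF32	(0, 1)	(1, 1)	100.00	100.00	100.00	100.00
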