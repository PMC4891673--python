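sample	I	II	III	IV
TTT	489	140	292	5
GS1-1	503	135	283	5
GS1-2	508	134	281	3
GS1-3	509	132	280	5
GS1-4	499	134	289	4
GS1-5	497	136	288	5
GS1-6	506	132	284	4
GS1-7	491	135	295	5
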