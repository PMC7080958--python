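chr1	30000000	32000000	NFR_demo_1
chr4	100000000	102500000	NFR_demo_2
chr5	120000000	121500000	NFR_demo_3
chr10	70000000	72000000	NFR_demo_4
chr12	55000000	57000000	NFR_demo_5
chr18	40000000	41800000	NFR_demo_6
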