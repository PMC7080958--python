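chr2	170000000	171200000	FRA2G_like
chr3	60400000	61600000	FRA3B_like
chr6	161000000	162700000	FRA6E_like
chr7	130100000	131000000	FRA7H_like
chr16	78100000	78600000	FRA16D_like
chrX	146900000	147100000	FRAXA_like
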