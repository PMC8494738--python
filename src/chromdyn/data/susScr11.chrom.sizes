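chr1	274330532
chr2	151935994
chr3	132848913
chr4	130910915
chr5	104526007
chr6	170843587
chr7	121844099
chr8	138966237
chr9	139512083
chr10	69359453
chr11	79169978
chr12	61602749
chr13	208334590
chr14	141755446
chr15	140412725
chr16	79944280
chr17	63494081
chr18	55982971
chrX	125939595
chrY	43547828
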