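population	wild_type	im	no_phenotype
1	270	80	16
2	1299	469	112
3	560	159	16
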