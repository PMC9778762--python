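part,start,end,length,at_pct,gc_pct
I,1,327,327,49.8,50.2
II,328,653,326,57.1,42.9
III,654,980,327,72.2,27.8
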