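ecrh,p0e5,part,at,gc
0.581,1.02,I,0,3
0.581,1.02,II,0,0
0.581,1.02,III,0,0
0.582,0.99,I,0,18
0.582,0.99,II,0,0
0.582,0.99,III,0,0
0.583,0.96,I,26,63
0.583,0.96,II,0,5
0.583,0.96,III,0,0
0.584,0.93,I,77,69
0.584,0.93,II,20,33
0.584,0.93,III,0,0
0.585,0.84,I,77,69
0.585,0.84,II,106,75
0.585,0.84,III,75,32
0.586,0,I,134,82
0.586,0,II,127,82
0.586,0,III,236,91
0.587,0,I,163,149
0.587,0,II,178,93
0.587,0,III,236,91
0.588,0,I,163,164
0.588,0,II,186,134
0.588,0,III,236,91
0.589,0,I,163,164
0.589,0,II,186,140
0.589,0,III,236,91
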