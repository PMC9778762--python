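ecrh,p0e5,pimaxe5,part,at,gc
0.581,1.02,1.09,I,0,0
0.581,1.02,1.09,II,1,14
0.581,1.02,1.09,III,0,0
0.582,0.99,1.07,I,0,10
0.582,0.99,1.07,II,4,41
0.582,0.99,1.07,III,0,0
0.583,0.96,1.05,I,0,2
0.583,0.96,1.05,II,4,39
0.583,0.96,1.05,III,0,0
0.584,0.93,1.03,I,0,1
0.584,0.93,1.03,II,1,27
0.584,0.93,1.03,III,0,0
0.585,0.84,1,I,0,21
0.585,0.84,1,II,17,49
0.585,0.84,1,III,0,0
0.586,0,0.97,I,12,53
0.586,0,0.97,II,56,53
0.586,0,0.97,III,0,0
0.587,0,0.94,I,0,15
0.587,0,0.94,II,8,47
0.587,0,0.94,III,0,0
0.588,0,0.89,I,0,0
0.588,0,0.89,II,0,6
0.588,0,0.89,III,0,0
0.589,0,0,I,0,0
0.589,0,0,II,0,0
0.589,0,0,III,0,0
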