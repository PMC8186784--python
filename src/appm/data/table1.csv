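allele,label1,label0,train,test,under,over
A*01:01,3398,48700,45498,6600,1,2
A*02:01,6779,165342,160921,11200,0.8,3
A*02:03,1780,116299,107879,10200,0.8,3
A*02:07,3206,232783,225389,10600,0.7,5
A*03:01,5419,83117,77536,11000,1,3
A*11:01,2114,123143,114857,10400,0.8,3
A*24:02,5189,142382,136571,11000,0.7,3
A*29:02,1149,54125,49074,6200,1,5
A*31:01,1879,45918,41597,6200,1,4
A*32:01,584,40401,34885,6100,1,5
A*68:02,1516,92678,83994,10200,0.8,3
B*07:02,3162,201778,194340,10600,0.6,3
B*15:01,1684,106482,97966,10200,0.8,3
B*35:01,1019,53819,48638,6200,1,4
B*40:01,1321,80192,71313,10200,0.9,3
B*44:02,1525,44760,40085,6200,1,4
B*44:03,1487,39482,34769,6200,1,4
B*51:01,2597,77898,70095,10400,1,4
B*54:01,969,65623,56412,10180,1,3
B*57:01,1599,51562,46961,6200,1,4
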