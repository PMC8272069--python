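serial,least_squares,aamed,elsd,ours,ground_truth
1,530,537,560,542,545
2,545,540,540,548,550
3,589,595,595,599,603
4,600,587,590,591,593
5,570,570,571,576,577
6,564,561,561,563,569
7,553,573,569,575,573
8,575,587,584,578,581
9,573,579,570,573,573
10,555,562,560,570,569
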