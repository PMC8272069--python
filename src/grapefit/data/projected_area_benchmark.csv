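serial,least_squares,aamed,elsd,ours,ground_truth
1,304285,315765,305894,315951,318959
2,342628,347598,342146,347561,345793
3,274105,289075,274589,289014,288606
4,220553,216800,201454,216859,219015
5,238936,242457,245896,241367,242047
6,199784,204784,203654,205657,203955
7,55334,55697,54356,53738,54728
8,39128,42475,40289,39418,40242
9,54456,53457,53006,53982,53287
10,57055,57689,56126,56529,56224
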