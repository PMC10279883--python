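stage,W,N1,N2,N3,REM
W,17582,1354,415,28,484
N1,2085,4422,2805,50,1532
N2,869,1943,20853,1802,1834
N3,74,40,3194,13697,190
REM,546,1558,1263,25,7595
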