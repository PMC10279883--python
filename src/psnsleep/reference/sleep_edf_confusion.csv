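stage,W,N1,N2,N3,REM
W,6912,445,136,28,213
N1,585,993,566,15,625
N2,603,500,15192,598,777
N3,157,5,672,4856,6
REM,358,817,867,4,5670
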