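parasite_genotype,A1hA1hB1hB1h,A1hA1hB1hB2h,A1hA1hB2hB2h,A1hA2hB1hB1h,A1hA2hB1hB2h,A1hA2hB2hB2h,A2hA2hB1hB1h,A2hA2hB1hB2h,A2hA2hB2hB2h
A1pA1pB1pB1p,I,I,R,I,I,R,R,R,R
A1pA1pB1pB2p,R,R,I,R,R,I,R,R,R
A1pA1pB2pB2p,R,R,I,R,R,I,R,R,R
A1pA2pB1pB1p,R,R,R,R,R,R,I,I,R
A1pA2pB1pB2p,R,R,R,R,R,R,R,R,I
A1pA2pB2pB2p,R,R,R,R,R,R,R,R,I
A2pA2pB1pB1p,R,R,R,R,R,R,I,I,R
A2pA2pB1pB2p,R,R,R,R,R,R,R,R,I
A2pA2pB2pB2p,R,R,R,R,R,R,R,R,I
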