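name	markers
mix1	D11S1338,D11S2351,D6S1624,HLAC-CA,MIB,DQCAR,RING3-CA
mix2	D11S1338,D11S2351,MOG-CA,D6S265,D6S273,DRA-CA,TAP1-CA
mix3	D11S4891,D11S4181,D6S1624,HLAC-CA,MIB,DRA-CA,TAP1-CA
mix4	D11S1760,D11S4181,MOG-CA,D6S265,D6S273,DQCAR,RING3-CA
mix5	D11S4891,D11S1871,D6S1571,D6S265,MIB,D6S2443,D6S1583
mix6	D11S1760,D11S1871,MOG-TAAA,HLAC-CA,D6S273,D6S2443,D6S1610
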