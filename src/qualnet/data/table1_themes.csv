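theme_id,label
1,Ethics and PM
2,Decision-making and PM
3,Effectiveness evidence and PM
4,Interpretation of PM
5,HC systems/public health and PM
6,Challenges in PM
7,Patient-doctor relationships and PM
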