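config_id,volume_mm3
Comp.,254145
Comp.,239256
Comp.,277954
Comp.,286303
1/2 Acc.,304247
1/2 Acc.,305351
1/2 Acc.,272516
1/2 Acc.,277740
1/4 Acc.,262466
1/4 Acc.,286887
1/4 Acc.,279901
1/4 Acc.,274849
1/8 Acc.,295410
1/8 Acc.,310579
1/8 Acc.,291054
1/8 Acc.,304708
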