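# disease_id	disease_label	phenotype_id
TOYD:0001	disease D1	TOY:0000004
TOYD:0002	disease D2	TOY:0000005
TOYD:0003	disease D3	TOY:0000003
TOYD:0004	disease D4	TOY:0000006
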