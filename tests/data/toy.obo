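format-version: 1.2
ontology: toy

[Term]
id: TOY:0000001
name: root phenotype

[Term]
id: TOY:0000002
name: phenotype A
is_a: TOY:0000001 ! root phenotype
alt_id: TOY:0000099

[Term]
id: TOY:0000003
name: phenotype B
is_a: TOY:0000001 ! root phenotype

[Term]
id: TOY:0000004
name: phenotype A1
is_a: TOY:0000002 ! phenotype A

[Term]
id: TOY:0000005
name: phenotype A2
is_a: TOY:0000002 ! phenotype A

[Term]
id: TOY:0000006
name: phenotype A1a
is_a: TOY:0000004 ! phenotype A1

[Term]
id: TOY:0000090
name: withdrawn phenotype
is_obsolete: true
is_a: TOY:0000002
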