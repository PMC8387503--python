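# Extended dietary fatty acid subset (39 names, C:DnX shorthand).
# Editable: replace with the panel used by your laboratory.
14:0
14:1n5
15:0
16:1n7
16:1n5
16:2n6
16:2n4
16:3n6
16:3n4
16:4n3
16:4n1
17:1
18:1n9
18:1n7
18:1n5
18:2n6
18:2n4
18:3n6
18:3n4
18:3n3
18:3n1
18:4n3
18:4n1
20:1n11
20:1n9
20:1n7
20:2n6
20:3n6
20:3n3
20:4n6
20:4n3
20:5n3
21:5n3
22:1n11
22:1n9
22:1n7
22:4n6
22:5n3
22:6n3
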