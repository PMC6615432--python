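taxon	rank	mean_copy_number
Agathobaculum	genus	4.4
Akkermansia	genus	4.0
Bacteroides	genus	5.5
Blautia	genus	10.0
Clostridium	genus	5.9
Coprococcus	genus	9.8
Eggerthella	genus	7.2
Escherichia	genus	4.8
Eubacterium	genus	5.5
Faecalibacterium	genus	6.3
Finegoldia	genus	5.4
Flavonifractor	genus	8.6
Flintibacter	genus	9.5
Muribaculum	genus	5.0
Murimonas	genus	2.1
Parabacteroides	genus	6.9
Peptoniphilus	genus	4.8
Phascolarctobacterium	genus	8.4
Pseudoflavonifractor	genus	6.2
Ruminococcus	genus	4.6
Sutterella	genus	6.6
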