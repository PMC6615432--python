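genome_id	species	genus	family	B1	B2	B3	B5	B6	B7	B9	B12
Bacteroides thetaiotaomicron.g1	Bacteroides thetaiotaomicron	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides thetaiotaomicron.g2	Bacteroides thetaiotaomicron	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides thetaiotaomicron.g3	Bacteroides thetaiotaomicron	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Escherichia fergusonii.g1	Escherichia fergusonii	Escherichia	Escherichiaaceae	1	1	1	1	1	1	1	0
Escherichia fergusonii.g2	Escherichia fergusonii	Escherichia	Escherichiaaceae	1	1	1	1	1	1	1	0
Escherichia fergusonii.g3	Escherichia fergusonii	Escherichia	Escherichiaaceae	1	1	1	1	1	1	1	0
Escherichia fergusonii.g4	Escherichia fergusonii	Escherichia	Escherichiaaceae	1	1	1	1	1	1	1	0
Escherichia fergusonii.g5	Escherichia fergusonii	Escherichia	Escherichiaaceae	1	1	1	1	1	1	1	0
Flavonifractor plautii.g1	Flavonifractor plautii	Flavonifractor	Flavonifractoraceae	0	0	0	0	0	0	0	1
Flavonifractor plautii.g2	Flavonifractor plautii	Flavonifractor	Flavonifractoraceae	0	0	0	0	0	0	0	1
Flavonifractor plautii.g3	Flavonifractor plautii	Flavonifractor	Flavonifractoraceae	0	0	0	0	0	0	0	1
Peptoniphilus grossensis.g1	Peptoniphilus grossensis	Peptoniphilus	Peptoniphilusaceae	0	1	1	0	0	0	1	0
Peptoniphilus grossensis.g2	Peptoniphilus grossensis	Peptoniphilus	Peptoniphilusaceae	0	1	0	0	0	0	1	0
Finegoldia magna.g1	Finegoldia magna	Finegoldia	Finegoldiaaceae	1	0	0	0	1	0	1	0
Finegoldia magna.g2	Finegoldia magna	Finegoldia	Finegoldiaaceae	1	0	0	0	1	0	1	0
Finegoldia magna.g3	Finegoldia magna	Finegoldia	Finegoldiaaceae	1	0	0	0	1	0	1	0
Finegoldia magna.g4	Finegoldia magna	Finegoldia	Finegoldiaaceae	1	0	0	0	1	0	1	0
Finegoldia magna.g5	Finegoldia magna	Finegoldia	Finegoldiaaceae	1	0	0	0	1	0	1	0
Finegoldia magna.g6	Finegoldia magna	Finegoldia	Finegoldiaaceae	1	0	0	0	1	0	1	0
Bacteroides faecis.g1	Bacteroides faecis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides faecis.g2	Bacteroides faecis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides vulgatus.g1	Bacteroides vulgatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides vulgatus.g2	Bacteroides vulgatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides vulgatus.g3	Bacteroides vulgatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides vulgatus.g4	Bacteroides vulgatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides vulgatus.g5	Bacteroides vulgatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides vulgatus.g6	Bacteroides vulgatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides caccae.g1	Bacteroides caccae	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides caccae.g2	Bacteroides caccae	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides caccae.g3	Bacteroides caccae	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Clostridium perfringens.g1	Clostridium perfringens	Clostridium	Clostridiumaceae	1	1	1	0	0	0	1	1
Clostridium perfringens.g2	Clostridium perfringens	Clostridium	Clostridiumaceae	1	1	1	0	0	0	1	1
Clostridium perfringens.g3	Clostridium perfringens	Clostridium	Clostridiumaceae	1	1	1	0	0	0	1	1
Clostridium perfringens.g4	Clostridium perfringens	Clostridium	Clostridiumaceae	1	1	1	0	0	0	1	1
Phascolarctobacterium sp. PB01.g1	Phascolarctobacterium sp. PB01	Phascolarctobacterium	Phascolarctobacteriumaceae	1	1	0	1	1	1	1	1
Bacteroides massiliensis.g1	Bacteroides massiliensis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides uniformis.g1	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides uniformis.g2	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides uniformis.g3	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides uniformis.g4	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides uniformis.g5	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides uniformis.g6	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Bacteroides uniformis.g7	Bacteroides uniformis	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	1
Agathobaculum desmolans.g1	Agathobaculum desmolans	Agathobaculum	Agathobaculumaceae	0	0	0	0	0	0	0	1
Akkermansia muciniphila.g1	Akkermansia muciniphila	Akkermansia	Akkermansiaaceae	1	1	1	1	1	1	1	1
Akkermansia muciniphila.g2	Akkermansia muciniphila	Akkermansia	Akkermansiaaceae	1	1	1	1	1	1	1	0
Akkermansia muciniphila.g3	Akkermansia muciniphila	Akkermansia	Akkermansiaaceae	1	1	1	1	1	1	1	0
Akkermansia muciniphila.g4	Akkermansia muciniphila	Akkermansia	Akkermansiaaceae	1	1	1	1	1	1	1	0
Pseudoflavonifractor capillosus.g1	Pseudoflavonifractor capillosus	Pseudoflavonifractor	Pseudoflavonifractoraceae	0	0	0	0	0	0	0	1
Pseudoflavonifractor sp. PB02.g1	Pseudoflavonifractor sp. PB02	Pseudoflavonifractor	Pseudoflavonifractoraceae	0	1	0	0	0	0	0	0
Pseudoflavonifractor sp. PB02.g2	Pseudoflavonifractor sp. PB02	Pseudoflavonifractor	Pseudoflavonifractoraceae	0	1	0	0	0	0	0	0
Bacteroides ovatus.g1	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides ovatus.g2	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides ovatus.g3	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides ovatus.g4	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides ovatus.g5	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides ovatus.g6	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Bacteroides ovatus.g7	Bacteroides ovatus	Bacteroides	Bacteroidesaceae	1	1	1	1	1	1	1	0
Parabacteroides merdae.g1	Parabacteroides merdae	Parabacteroides	Parabacteroidesaceae	1	1	1	1	1	1	1	1
Parabacteroides merdae.g2	Parabacteroides merdae	Parabacteroides	Parabacteroidesaceae	1	1	1	1	1	1	1	1
Parabacteroides merdae.g3	Parabacteroides merdae	Parabacteroides	Parabacteroidesaceae	1	1	1	1	1	1	1	1
Parabacteroides merdae.g4	Parabacteroides merdae	Parabacteroides	Parabacteroidesaceae	1	1	1	1	1	1	1	1
Eggerthella lenta.g1	Eggerthella lenta	Eggerthella	Eggerthellaaceae	1	0	0	1	1	0	1	0
Eggerthella lenta.g2	Eggerthella lenta	Eggerthella	Eggerthellaaceae	1	0	0	1	1	0	1	0
Eggerthella lenta.g3	Eggerthella lenta	Eggerthella	Eggerthellaaceae	1	0	0	0	1	0	1	0
Flintibacter butyricus.g1	Flintibacter butyricus	Flintibacter	Flintibacteraceae	0	0	0	0	0	0	0	1
Flintibacter butyricus.g2	Flintibacter butyricus	Flintibacter	Flintibacteraceae	0	0	0	0	0	0	0	1
Flintibacter butyricus.g3	Flintibacter butyricus	Flintibacter	Flintibacteraceae	0	0	0	0	0	0	0	1
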