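taxon	rank	trait
Ciliophora	division	consumer
Cercozoa	division	consumer
Amoebozoa	supergroup	consumer
Heterolobosea	division	consumer
Bicosoecida	order	consumer
Bigyra	division	consumer
Hypotrichia	order	consumer
Oxytricha	genus	consumer
Colpoda	genus	consumer
Cercomonas	genus	consumer
Chlorophyta	division	phototrophic
Trebouxiophyceae	class	phototrophic
Chlorophyceae	class	phototrophic
Bacillariophyta	class	phototrophic
Chrysophyceae	class	phototrophic
Rhodophyta	division	phototrophic
Scenedesmus	genus	phototrophic
Apicomplexa	division	parasitic
Gregarinomorphea	class	parasitic
Perkinsea	division	parasitic
Peronosporomycetes	class	parasitic
Oomycota	division	parasitic
Pythium	genus	parasitic
Phytophthora	genus	parasitic
Plasmodiophorida	order	parasitic
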