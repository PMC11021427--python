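lulc,habitat,Agriculture land,Livestock grazing,Urban land,Rural land,Mining land,Main roads,Minor roads
Zagros forest,1,0.70,0.61,0.74,0.70,0.80,0.85,0.70
Rangeland/good,1,0.75,0.82,0.68,0.70,0.81,0.85,0.70
Rangeland/fair,0.8,0.84,0.84,0.68,0.70,0.81,0.73,0.70
Rangeland/poor,0.6,0.84,0.71,0.54,0.70,0.80,0.73,0.70
Water bodies,0.5,0.40,0,0,0,0,0.35,0.35
Agriculture,0.2,0,0.30,0.70,0.75,0.85,0.50,0.65
Build up area,0,0,0,0,0,0,0.60,0.50
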