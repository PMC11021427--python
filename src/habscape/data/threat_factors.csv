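threat,max_dist_km,weight,decay
Agriculture land,8,0.82,linear
Livestock grazing,6,0.72,linear
Urban land,8,0.31,exponential
Rural land,8,0.51,exponential
Mining land,10,0.69,exponential
Main roads,7,0.50,linear
Minor roads,5,0.50,linear
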