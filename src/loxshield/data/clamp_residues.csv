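enzyme,pos1,pos2,pos3,pos4,pos5,pos6,main_product
CspLOX2,Leu258,Ile296,Ala300,Leu304,Leu502,Leu506,11R
CspLOX1,Tyr360,Ile397,Gly401,Leu405,Ile617,Leu621,9R
coral 8R-LOX,Leu758,Ile796,Gly800,Leu804,Thr996,Leu1000,8R
human 15S-LOX,Leu361,Ile399,Ala403,Leu407,Ile592,Leu596,15S
P. aeruginosa LOX2,Leu378,Ile416,Ala420,Leu424,Ile608,Leu612,15S
13R-Mn-LOX (G. graminis),Val291,Ile328,Gly332,Leu336,Leu535,Phe539,13R
9R-Mn-LOX (M. salvinii),Val299,Val337,Gly341,Leu345,Leu536,Phe540,9R
soybean LOX-1,Trp500,Ile538,Ala542,Leu546,Val750,Leu754,13S
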