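strain,titer,productivity,yield,feed,source
C. curvatus,86.1,0.47,0.25,glucose,Zhang
E. coli,1.1,0.0153,0.024,glucose,Yan
E. coli,1.2,0.0167,0.063,glucose,Yan
E. coli,7.2,0.075,0.049,glucose,Yan
L. starkeyi,17.58,0.1465,N/A,glucose,Zhang
M. pulcherrima,26.9,0.13,0.07,glucose,Abeln & Chuck
M. pulcherrima,28.3,0.08,0.11,glucose,Abeln & Chuck
M. pulcherrima,44.8,0.12,0.13,glucose,Abeln & Chuck
M. pulcherrima,50.6,0.16,0.16,glucose,Abeln & Chuck
P. putida,0.029,0.0006,0.0003,glucose,Valencia et al.
P. putida,0.224,0.0047,N/A,glucose,Valencia et al.
P. putida,0.259,0.0054,0.0016,glucose,Valencia et al.
P. putida,0.279,0.0058,N/A,glucose,Valencia et al.
P. putida,0.486,0.0101,N/A,glucose,Valencia et al.
P. putida,0.67,0.014,N/A,glucose,Valencia et al.
R. fluvialis,23.6,0.984,0.33,glycerol,Poontawee & Limtong
R. opacus,14.3,0.085,0.279,glucose,Qiao et al.
R. toruloides,67.5,0.54,0.23,glucose,Li et al.
R. toruloides,78.7,0.57,0.23,glucose,Zhao et al.
S. terricola,13.81,0.0575,N/A,glucose,Aiello et al.
T. oleaginosus,16.2,0.41,0.31,hydrolysate,Meo et al.
T. oleaginosus,18.6,0.25,0.13,hydrolysate,Meo et al.
T. oleaginosus,20.4,0.28,0.11,hydrolysate,Meo et al.
T. oleaginosus,21,0.29,0.11,hydrolysate,Meo et al.
T. oleaginosus,30.6,0.31,0.43,hydrolysate,Meo et al.
T. oleaginosus,8.9,0.12,0.09,hydrolysate,Meo et al.
Y. lipolytica,0.242,0.001,0.0466,glucose,Li et al.
Y. lipolytica,0.319,0.0012,0.0057,glucose,Li et al.
Y. lipolytica,1.2,0.0031,0.0964,glucose,Li et al.
Y. lipolytica,1.47,0.0027,0.0888,glucose,Li et al.
Y. lipolytica,12.5,0.1736,N/A,glucose,Wei et al.
Y. lipolytica,13.5,0.1875,N/A,glucose,Wei et al.
Y. lipolytica,2.9,N/A,N/A,glucose,Rutter et al.
Y. lipolytica,66.4,0.565,0.229,glucose,Xu et al.
Y. lipolytica,72.7,0.97,0.252,glucose,Xu et al.
Y. lipolytica,98.9,1.2,0.27,glucose,Qiao et al.
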