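acronym,index,module,has_L4
FRP,1,prefrontal,False
ACAd,2,prefrontal,False
ACAv,3,prefrontal,False
PL,4,prefrontal,False
ILA,5,prefrontal,False
ORBl,6,prefrontal,False
ORBm,7,prefrontal,False
ORBvl,8,prefrontal,False
AId,9,lateral,False
AIp,10,lateral,False
AIv,11,lateral,False
GU,12,lateral,True
VISC,13,lateral,True
TEa,14,lateral,True
PERI,15,lateral,False
ECT,16,lateral,False
MOp,17,somatomotor,False
MOs,18,somatomotor,False
SSp-n,19,somatomotor,True
SSp-bfd,20,somatomotor,True
SSp-ll,21,somatomotor,True
SSp-m,22,somatomotor,True
SSp-ul,23,somatomotor,True
SSp-tr,24,somatomotor,True
SSp-un,25,somatomotor,True
SSs,26,somatomotor,True
VISal,27,visual,True
VISam,28,visual,True
VISl,29,visual,True
VISp,30,visual,True
VISpl,31,visual,True
VISpm,32,visual,True
VISli,33,visual,True
VISpor,34,visual,True
VISa,35,visual,True
VISrl,36,visual,True
RSPagl,37,medial,False
RSPd,38,medial,False
RSPv,39,medial,False
AUDd,40,auditory,True
AUDp,41,auditory,True
AUDpo,42,auditory,True
AUDv,43,auditory,True
ENTl,44,medial,False
ENTm,45,medial,False
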