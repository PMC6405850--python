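# Constructed Miyazawa-Jernigan-style residue-residue contact potential.
# E(a,b) = -h(a)*h(b) - 0.6*[opposite formal charge] + 0.3*[same formal charge],
# h = Kyte-Doolittle hydropathy rescaled to [0,1]. Arbitrary energy units;
# the frustration z-score is invariant to affine rescaling of this table.
res,ALA,ARG,ASN,ASP,CYS,GLN,GLU,GLY,HIS,ILE,LEU,LYS,MET,PHE,PRO,SER,THR,TRP,TYR,VAL
ALA,-0.4900,-0.0000,-0.0778,-0.0778,-0.5444,-0.0778,-0.0778,-0.3189,-0.1011,-0.7000,-0.6456,-0.0467,-0.4978,-0.5678,-0.2256,-0.2878,-0.2956,-0.2800,-0.2489,-0.6767
ARG,-0.0000,0.3000,-0.0000,-0.6000,-0.0000,-0.0000,-0.6000,-0.0000,-0.0000,-0.0000,-0.0000,0.3000,-0.0000,-0.0000,-0.0000,-0.0000,-0.0000,-0.0000,-0.0000,-0.0000
ASN,-0.0778,-0.0000,-0.0123,-0.0123,-0.0864,-0.0123,-0.0123,-0.0506,-0.0160,-0.1111,-0.1025,-0.0074,-0.0790,-0.0901,-0.0358,-0.0457,-0.0469,-0.0444,-0.0395,-0.1074
ASP,-0.0778,-0.6000,-0.0123,0.2877,-0.0864,-0.0123,0.2877,-0.0506,-0.0160,-0.1111,-0.1025,-0.6074,-0.0790,-0.0901,-0.0358,-0.0457,-0.0469,-0.0444,-0.0395,-0.1074
CYS,-0.5444,-0.0000,-0.0864,-0.0864,-0.6049,-0.0864,-0.0864,-0.3543,-0.1123,-0.7778,-0.7173,-0.0519,-0.5531,-0.6309,-0.2506,-0.3198,-0.3284,-0.3111,-0.2765,-0.7519
GLN,-0.0778,-0.0000,-0.0123,-0.0123,-0.0864,-0.0123,-0.0123,-0.0506,-0.0160,-0.1111,-0.1025,-0.0074,-0.0790,-0.0901,-0.0358,-0.0457,-0.0469,-0.0444,-0.0395,-0.1074
GLU,-0.0778,-0.6000,-0.0123,0.2877,-0.0864,-0.0123,0.2877,-0.0506,-0.0160,-0.1111,-0.1025,-0.6074,-0.0790,-0.0901,-0.0358,-0.0457,-0.0469,-0.0444,-0.0395,-0.1074
GLY,-0.3189,-0.0000,-0.0506,-0.0506,-0.3543,-0.0506,-0.0506,-0.2075,-0.0658,-0.4556,-0.4201,-0.0304,-0.3240,-0.3695,-0.1468,-0.1873,-0.1923,-0.1822,-0.1620,-0.4404
HIS,-0.1011,-0.0000,-0.0160,-0.0160,-0.1123,-0.0160,-0.0160,-0.0658,-0.0209,-0.1444,-0.1332,-0.0096,-0.1027,-0.1172,-0.0465,-0.0594,-0.0610,-0.0578,-0.0514,-0.1396
ILE,-0.7000,-0.0000,-0.1111,-0.1111,-0.7778,-0.1111,-0.1111,-0.4556,-0.1444,-1.0000,-0.9222,-0.0667,-0.7111,-0.8111,-0.3222,-0.4111,-0.4222,-0.4000,-0.3556,-0.9667
LEU,-0.6456,-0.0000,-0.1025,-0.1025,-0.7173,-0.1025,-0.1025,-0.4201,-0.1332,-0.9222,-0.8505,-0.0615,-0.6558,-0.7480,-0.2972,-0.3791,-0.3894,-0.3689,-0.3279,-0.8915
LYS,-0.0467,0.3000,-0.0074,-0.6074,-0.0519,-0.0074,-0.6074,-0.0304,-0.0096,-0.0667,-0.0615,0.2956,-0.0474,-0.0541,-0.0215,-0.0274,-0.0281,-0.0267,-0.0237,-0.0644
MET,-0.4978,-0.0000,-0.0790,-0.0790,-0.5531,-0.0790,-0.0790,-0.3240,-0.1027,-0.7111,-0.6558,-0.0474,-0.5057,-0.5768,-0.2291,-0.2923,-0.3002,-0.2844,-0.2528,-0.6874
PHE,-0.5678,-0.0000,-0.0901,-0.0901,-0.6309,-0.0901,-0.0901,-0.3695,-0.1172,-0.8111,-0.7480,-0.0541,-0.5768,-0.6579,-0.2614,-0.3335,-0.3425,-0.3244,-0.2884,-0.7841
PRO,-0.2256,-0.0000,-0.0358,-0.0358,-0.2506,-0.0358,-0.0358,-0.1468,-0.0465,-0.3222,-0.2972,-0.0215,-0.2291,-0.2614,-0.1038,-0.1325,-0.1360,-0.1289,-0.1146,-0.3115
SER,-0.2878,-0.0000,-0.0457,-0.0457,-0.3198,-0.0457,-0.0457,-0.1873,-0.0594,-0.4111,-0.3791,-0.0274,-0.2923,-0.3335,-0.1325,-0.1690,-0.1736,-0.1644,-0.1462,-0.3974
THR,-0.2956,-0.0000,-0.0469,-0.0469,-0.3284,-0.0469,-0.0469,-0.1923,-0.0610,-0.4222,-0.3894,-0.0281,-0.3002,-0.3425,-0.1360,-0.1736,-0.1783,-0.1689,-0.1501,-0.4081
TRP,-0.2800,-0.0000,-0.0444,-0.0444,-0.3111,-0.0444,-0.0444,-0.1822,-0.0578,-0.4000,-0.3689,-0.0267,-0.2844,-0.3244,-0.1289,-0.1644,-0.1689,-0.1600,-0.1422,-0.3867
TYR,-0.2489,-0.0000,-0.0395,-0.0395,-0.2765,-0.0395,-0.0395,-0.1620,-0.0514,-0.3556,-0.3279,-0.0237,-0.2528,-0.2884,-0.1146,-0.1462,-0.1501,-0.1422,-0.1264,-0.3437
VAL,-0.6767,-0.0000,-0.1074,-0.1074,-0.7519,-0.1074,-0.1074,-0.4404,-0.1396,-0.9667,-0.8915,-0.0644,-0.6874,-0.7841,-0.3115,-0.3974,-0.4081,-0.3867,-0.3437,-0.9344
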