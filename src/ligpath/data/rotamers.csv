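resname,rotamer,chi1,chi2,chi3,chi4,probability
ARG,0,-67,180,180,180,0.35
ARG,1,-177,180,180,180,0.30
ARG,2,-67,-167,-65,-175,0.20
ASN,0,-65,-65,,,0.35
ASN,1,-177,-65,,,0.25
ASN,2,-65,120,,,0.20
ASP,0,-70,-15,,,0.45
ASP,1,-177,0,,,0.30
ASP,2,-65,65,,,0.15
CYS,0,-65,,,,0.50
CYS,1,-177,,,,0.30
CYS,2,63,,,,0.20
GLN,0,-67,180,-25,,0.35
GLN,1,-177,65,-40,,0.25
GLN,2,-65,-65,-40,,0.20
GLU,0,-67,180,-10,,0.40
GLU,1,-177,180,0,,0.30
GLU,2,-65,-65,-40,,0.20
HIS,0,-65,-70,,,0.40
HIS,1,-177,65,,,0.30
HIS,2,63,-75,,,0.20
ILE,0,-65,170,,,0.60
ILE,1,-57,-60,,,0.15
ILE,2,62,170,,,0.15
LEU,0,-65,175,,,0.60
LEU,1,-177,65,,,0.30
LEU,2,-85,65,,,0.10
LYS,0,-67,180,180,180,0.40
LYS,1,-177,180,180,180,0.30
LYS,2,-90,180,180,180,0.20
MET,0,-65,-65,-70,,0.30
MET,1,-177,180,75,,0.30
MET,2,-67,180,180,,0.30
PHE,0,-65,90,,,0.50
PHE,1,-177,80,,,0.35
PHE,2,62,90,,,0.15
SER,0,64,,,,0.45
SER,1,-65,,,,0.30
SER,2,-177,,,,0.25
THR,0,62,,,,0.50
THR,1,-60,,,,0.40
THR,2,-175,,,,0.10
TRP,0,-65,95,,,0.35
TRP,1,-177,-105,,,0.30
TRP,2,62,-90,,,0.20
TYR,0,-65,90,,,0.50
TYR,1,-177,80,,,0.35
TYR,2,62,90,,,0.15
VAL,0,175,,,,0.72
VAL,1,-60,,,,0.20
VAL,2,64,,,,0.08
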