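# Bead-to-species and bead-to-moiety mapping for CG (MARTINI-style) topologies.
# Editable: parsing never hard-codes bead names, it resolves them through this
# table (bead name patterns are fnmatch globs, first match wins).
#
# [species]  <residue-name> <species>
# [moiety]   <species> <bead-name-glob> <moiety>

[species]
POPC POPC
PPC  PPC
LPC  PPC
CHOL CHOL
CHO  CHOL
CE   CE
CHYO CE
TG   TG
TO   TG
W    WATER
WAT  WATER
SOL  WATER
ALA PROTEIN
ARG PROTEIN
ASN PROTEIN
ASP PROTEIN
CYS PROTEIN
GLN PROTEIN
GLU PROTEIN
GLY PROTEIN
HIS PROTEIN
ILE PROTEIN
LEU PROTEIN
LYS PROTEIN
MET PROTEIN
PHE PROTEIN
PRO PROTEIN
SER PROTEIN
THR PROTEIN
TRP PROTEIN
TYR PROTEIN
VAL PROTEIN

[moiety]
POPC NC3 headgroup
POPC PO4 headgroup
POPC GL* glycerol
POPC ?1A sn1_chain
POPC ?2A sn1_chain
POPC ?3A sn1_chain
POPC ?4A sn1_chain
POPC ?1B sn2_chain
POPC ?2B sn2_chain
POPC ?3B sn2_chain
POPC ?4B sn2_chain
PPC NC3 headgroup
PPC PO4 headgroup
PPC GL* glycerol
PPC ??A sn1_chain
CHOL ROH sterol_ring
CHOL R?  sterol_ring
CHOL C?  sterol_tail
CE ES  ester
CE R?  sterol_ring
CE C?  oleate_chain
TG GL  glycerol
TG ES? ester
TG ??A sn1_chain
TG ??B sn2_chain
TG ??C sn3_chain
PROTEIN BB  backbone
PROTEIN SC* sidechain
WATER W other
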