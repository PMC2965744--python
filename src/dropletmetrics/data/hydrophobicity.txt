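# Residue hydrophobicity classes for contact roll-ups and SASA partitioning.
# Two classes only; Tyr and His are amphipathic aromatics whose interfacial
# hydrophobicity rivals Phe, but they stay in the hydrophilic class under the
# standard two-way split.  Editable.
ALA hydrophobic
VAL hydrophobic
LEU hydrophobic
ILE hydrophobic
MET hydrophobic
PHE hydrophobic
TRP hydrophobic
ARG hydrophilic
ASN hydrophilic
ASP hydrophilic
CYS hydrophilic
GLN hydrophilic
GLU hydrophilic
GLY hydrophilic
HIS hydrophilic
LYS hydrophilic
PRO hydrophilic
SER hydrophilic
THR hydrophilic
TYR hydrophilic
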