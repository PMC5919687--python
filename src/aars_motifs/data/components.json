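{
  "ATP": {"adenosine_phosphate": true, "amino_acid_part": false},
  "ADP": {"adenosine_phosphate": true, "amino_acid_part": false},
  "AMP": {"adenosine_phosphate": true, "amino_acid_part": false},
  "ANP": {"adenosine_phosphate": true, "amino_acid_part": false},
  "ACP": {"adenosine_phosphate": true, "amino_acid_part": false},
  "AGS": {"adenosine_phosphate": true, "amino_acid_part": false},
  "APC": {"adenosine_phosphate": true, "amino_acid_part": false},
  "A": {"adenosine_phosphate": true, "amino_acid_part": false},
  "ALA": {"adenosine_phosphate": false, "amino_acid_part": true},
  "ARG": {"adenosine_phosphate": false, "amino_acid_part": true},
  "ASN": {"adenosine_phosphate": false, "amino_acid_part": true},
  "ASP": {"adenosine_phosphate": false, "amino_acid_part": true},
  "CYS": {"adenosine_phosphate": false, "amino_acid_part": true},
  "GLN": {"adenosine_phosphate": false, "amino_acid_part": true},
  "GLU": {"adenosine_phosphate": false, "amino_acid_part": true},
  "GLY": {"adenosine_phosphate": false, "amino_acid_part": true},
  "HIS": {"adenosine_phosphate": false, "amino_acid_part": true},
  "ILE": {"adenosine_phosphate": false, "amino_acid_part": true},
  "LEU": {"adenosine_phosphate": false, "amino_acid_part": true},
  "LYS": {"adenosine_phosphate": false, "amino_acid_part": true},
  "MET": {"adenosine_phosphate": false, "amino_acid_part": true},
  "PHE": {"adenosine_phosphate": false, "amino_acid_part": true},
  "PRO": {"adenosine_phosphate": false, "amino_acid_part": true},
  "SER": {"adenosine_phosphate": false, "amino_acid_part": true},
  "THR": {"adenosine_phosphate": false, "amino_acid_part": true},
  "TRP": {"adenosine_phosphate": false, "amino_acid_part": true},
  "TYR": {"adenosine_phosphate": false, "amino_acid_part": true},
  "VAL": {"adenosine_phosphate": false, "amino_acid_part": true}
}
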