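{
  "version": 1,
  "comment": "Pinned SMARTS for metal-coordinating (donor) atom detection, one pattern set per ligand charge class. Neutral: carbenes, phosphines, amines, oxygens. Anionic: hydroxides/alkoxides, amides, halides, sp3/sp2 carbanions.",
  "neutral": {
    "carbene_C": "[#6+0;X2;H0;!$([#6]=*);!$([#6]#*)]",
    "phosphine_P": "[#15+0;X3]",
    "amine_N_sp3": "[#7+0;X3;!$([#7]=*);!$([#7]#*)]",
    "aromatic_N": "[n+0;X2]",
    "imine_N": "[#7+0;X2;$([#7]=[#6])]",
    "ether_O": "[#8+0;X2]",
    "carbonyl_O": "[#8+0;X1;$([#8]=[#6])]"
  },
  "anionic": {
    "oxide_O": "[#8;-1]",
    "amide_N": "[#7;-1]",
    "halide_X": "[F-,Cl-,Br-,I-]",
    "carbanion_C": "[#6;-1]"
  }
}
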