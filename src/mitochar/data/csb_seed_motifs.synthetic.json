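{
  "_comment": "Synthetic seed motifs for the four conserved sequence blocks of the teleost mitochondrial control region. Block lengths (CSB-D 18 bp, CSB-1 21 bp, CSB-2 18 bp, CSB-3 20 bp) follow published comparative work on cyprinid control regions; the motif sequences themselves are synthetic stand-ins used by the simulator and test fixtures, not empirical consensus calls.",
  "CSB-D": "TACTATTAATGGTCTAGT",
  "CSB-1": "ATAATGTCTAATACCATTAGT",
  "CSB-2": "AAACCCCCCTACCCCCCT",
  "CSB-3": "TGCCAAACCCCGAAACCAAG"
}
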