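panel:
  - gene: ABCA4
    inheritance_mode: AR
    phenotype_group: STGD
  - gene: ELOVL4
    inheritance_mode: AD
    phenotype_group: STGD
  - gene: PROM1
    inheritance_mode: AR
    phenotype_group: STGD
  - gene: PRPH2
    inheritance_mode: AD
    phenotype_group: STGD
  - gene: BEST1
    inheritance_mode: AD
    phenotype_group: STGD
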