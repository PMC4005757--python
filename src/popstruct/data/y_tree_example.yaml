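# Example Y-chromosome haplogroup tree configuration.
#
# parent: child -> parent edges over haplogroup labels (free strings,
# matched case-sensitively).  reduced_level: the designated comparison
# level to which observed sub-haplogroups are collapsed when datasets of
# different SNP resolution are combined (a 21-lineage paternal level is a
# typical cross-study choice).  This file is an editable template, not a
# complete phylogeny.
parent:
  E-V12: E-M78
  E-V13: E-M78
  E-V22: E-M78
  E-M78: E-M35
  E-M81: E-M35
  E-M123: E-M35
  G-P16: G-P15
  G-P15: G-M201
  G-M286: G-M201
  I-M253: I-M170
  I-M223: I-M170
  I-M26: I-M170
  J-M410: J-M172
  J-M67: J-M410
  J-M92: J-M67
  J-M12: J-M172
  J-M172: J-M304
  J-M267: J-M304
  R-M17: R-M173
  R-M343: R-M173
  R-M269: R-M343
  R-L51: R-M269
  R-L11: R-L51
  R-U106: R-L11
  R-P312: R-L11
  R-U152: R-P312
  R-L2: R-U152
  R-L21: R-P312
  R-M167: R-P312
reduced_level:
  - E-V12
  - E-V13
  - E-V22
  - E-M81
  - E-M123
  - G-M201
  - I-M253
  - I-M223
  - I-M26
  - J-M410
  - J-M67
  - J-M92
  - J-M12
  - J-M267
  - R-M17
  - R-M269
  - R-U106
  - R-P312
  - R-U152
  - K-M9
  - F-M89
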