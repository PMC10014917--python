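# Diplotype-to-phenotype combination rules per guideline system.
# Keys are unordered pairs of allele function classes, written sorted and
# joined by "|".  Any combination not listed maps to "indeterminate".
CPIC:
  categories: [PM, IM, NM, RM, UM]
  combinations:
    no_function|no_function: PM
    no_function|normal: IM
    increased|no_function: IM
    decreased|no_function: IM
    decreased|decreased: IM
    decreased|normal: IM
    normal|normal: NM
    increased|normal: RM
    increased|increased: UM
DPWG:
  # DPWG does not use the Rapid Metabolizer category; an increased-function
  # allele paired with a normal one is reported NM with a carrier annotation.
  categories: [PM, IM, NM, UM]
  combinations:
    no_function|no_function: PM
    no_function|normal: IM
    increased|no_function: IM
    decreased|no_function: IM
    decreased|decreased: IM
    decreased|normal: IM
    normal|normal: NM
    increased|normal: NM
    increased|increased: UM
  annotations:
    increased|normal: increased-function carrier
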