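# b/tsDMARD mechanism-of-action taxonomy: WHO ATC code -> (drug, MoA class).
# Editable: add codes here to extend coverage. Codes absent from this file
# are treated as not_btsDMARD by the rule engine.
#
# class_order fixes the deterministic tie-break when two classes are first
# started on the same day.
class_order: [TNFi, IL6i, CTLA4Ig, antiCD20, JAKi, IL1i, other_btsDMARD]
codes:
  L04AB01: {drug: etanercept, moa: TNFi}
  L04AB02: {drug: infliximab, moa: TNFi}
  L04AB04: {drug: adalimumab, moa: TNFi}
  L04AB05: {drug: certolizumab pegol, moa: TNFi}
  L04AB06: {drug: golimumab, moa: TNFi}
  L04AC07: {drug: tocilizumab, moa: IL6i}
  L04AC14: {drug: sarilumab, moa: IL6i}
  L04AA24: {drug: abatacept, moa: CTLA4Ig}
  L01XC02: {drug: rituximab, moa: antiCD20}
  L04AA29: {drug: tofacitinib, moa: JAKi}
  L04AA37: {drug: baricitinib, moa: JAKi}
  L04AA44: {drug: upadacitinib, moa: JAKi}
  L04AA45: {drug: filgotinib, moa: JAKi}
  L04AC03: {drug: anakinra, moa: IL1i}
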