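# Lexicon for mining rheumatology clinic letters (English).
#
# These term lists are synthetic stand-ins assembled for this package's
# English letter templates; a deployment against real correspondence must
# replace them with locally curated (and language-appropriate) lists.
medication_terms:
  etanercept: {drug: etanercept, moa: TNFi}
  adalimumab: {drug: adalimumab, moa: TNFi}
  infliximab: {drug: infliximab, moa: TNFi}
  certolizumab: {drug: certolizumab pegol, moa: TNFi}
  certolizumab pegol: {drug: certolizumab pegol, moa: TNFi}
  golimumab: {drug: golimumab, moa: TNFi}
  tocilizumab: {drug: tocilizumab, moa: IL6i}
  sarilumab: {drug: sarilumab, moa: IL6i}
  abatacept: {drug: abatacept, moa: CTLA4Ig}
  rituximab: {drug: rituximab, moa: antiCD20}
  tofacitinib: {drug: tofacitinib, moa: JAKi}
  baricitinib: {drug: baricitinib, moa: JAKi}
  upadacitinib: {drug: upadacitinib, moa: JAKi}
  filgotinib: {drug: filgotinib, moa: JAKi}
  anakinra: {drug: anakinra, moa: IL1i}
activity_terms:
  - flare
  - active arthritis
  - active disease
  - exacerbation
  - synovitis
negation_cues:
  - "no"
  - "not"
  - without
  - denies
target_headings:
  - medication
  - dmard history
activity_headings:
  - conclusion
  - assessment
  - history
  - physical examination
negation_window: 3
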