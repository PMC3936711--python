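# Signature-gene map for CRISPR-Cas type/subtype assignment.
#
# role:
#   type_signature    — presence implies the type even with no subtype resolved
#   subtype_signature — presence implies the subtype (and its parent type)
#   generic           — known Cas family with no classification weight
#
# Subtype II-C carries no signature family: it is the minimal type II system
# defined by the exact known-cas composition {cas9, cas1, cas2}, and is only
# callable from complete genomes (on fragments, absence evidence is
# unreliable).  That rule lives in code, keyed by the ii_c block below.
families:
  cas3:    {type: I,   subtype: null,       role: type_signature}
  cas9:    {type: II,  subtype: null,       role: type_signature}
  cas10:   {type: III, subtype: null,       role: type_signature}
  csa5:    {type: I,   subtype: I-A,        role: subtype_signature}
  cas8b:   {type: I,   subtype: I-B,        role: subtype_signature}
  cas8c:   {type: I,   subtype: I-C,        role: subtype_signature}
  cas10d:  {type: I,   subtype: I-D,        role: subtype_signature}
  cse1:    {type: I,   subtype: I-E,        role: subtype_signature}
  csy1:    {type: I,   subtype: I-F,        role: subtype_signature}
  GSU0054: {type: I,   subtype: IC-variant, role: subtype_signature}
  GSU0053: {type: I,   subtype: IC-variant, role: subtype_signature}
  csn2:    {type: II,  subtype: II-A,       role: subtype_signature}
  # cas4 is II-B evidence only when cas9 is present in the same locus:
  # cas4 also occurs in type I systems.
  cas4:    {type: II,  subtype: II-B,       role: subtype_signature, requires: cas9}
  csm:     {type: III, subtype: III-A,      role: subtype_signature}
  cmr:     {type: III, subtype: III-B,      role: subtype_signature}
  cas1:    {type: null, subtype: null,      role: generic}
  cas2:    {type: null, subtype: null,      role: generic}
  cas5:    {type: null, subtype: null,      role: generic}
  cas6:    {type: null, subtype: null,      role: generic}
  cas7:    {type: null, subtype: null,      role: generic}
  RAMP:    {type: null, subtype: null,      role: generic}
ii_c:
  subtype: II-C
  type: II
  composition: [cas9, cas1, cas2]
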