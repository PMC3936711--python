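# Toxin and antitoxin family tags used for toxin-antitoxin pair detection
# inside cas loci.
toxins:
  - Fic
  - DOC
  - PIN
antitoxins:
  - PhdYeFM_antitox
  - Antitoxin-MazE
  - Unstab_antitox
  - TIGR02612
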