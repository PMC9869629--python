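# Example ontology/scoring configuration for `classlink`.
# Every key is optional; omitted keys keep the built-in defaults.
# Pass with `classlink build-tables --config <file>` or `load_config(path)`.

# Ontology levels entering the scoring tables (2 x 7 levels -> 28 tables).
genome_levels: [MIBIG_CLASS, ANTISMASH_CLASS]
structure_levels:
  [NPC_PATHWAY, NPC_SUPERCLASS, NPC_CLASS,
   CF_KINGDOM, CF_SUPERCLASS, CF_CLASS, CF_SUBCLASS]

# Entries below are MERGED into the built-in translation tables.
bigscape_to_mibig:
  PKSI: Polyketide
  PKSother: Polyketide
  PKS-NRP_Hybrids: Polyketide-NRP
  NRPS: NRP
  RiPPs: RiPP
  Saccharides: Saccharide
  Terpene: Terpene
  Others: Other

antismash_aliases:           # pre-v5 rule names -> v5 names
  transatpks: transAT-PKS
  otherks: PKS-like
  lantipeptide: lanthipeptide

# Genome-side labels containing a hybrid delimiter that must never be split.
# Uncommenting REPLACES the built-in list.
# protected_tokens: [Polyketide-NRP, transAT-PKS, transAT-PKS-like, NRPS-like, PKS-like]
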