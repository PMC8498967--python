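# Dialect table mapping annotation-tool classification tokens onto the
# hierarchical (Wicker-style) class/order/superfamily system used
# throughout the package.  Edit or extend to absorb naming drift between
# masking tools; unknown tokens always degrade to "unclassified" rather
# than erroring.

# Orders recognised per TE class.  Retrotransposons (Class I) transpose
# through an RNA intermediate; DNA transposons (Class II) do not.
orders:
  I: [LTR, DIRS, PLE, LINE, SINE]
  II: [TIR, Helitron, Maverick, Crypton]

# Alternative order spellings emitted by common tools.
order_aliases:
  DNA: TIR
  RC: Helitron
  ROLLING-CIRCLE: Helitron
  PENELOPE: PLE
  RETROPOSON: LINE
  NONLTR: LINE
  NON-LTR: LINE

# Alternative superfamily spellings (tool token -> canonical name).
superfamily_aliases:
  TCMAR-TC1: Tc1-Mariner
  TCMAR: Tc1-Mariner
  TC1_MARINER: Tc1-Mariner
  TC1/MARINER: Tc1-Mariner
  TC1: Tc1-Mariner
  MARINER: Tc1-Mariner
  EN-SPM: CACTA
  ENSPM: CACTA
  ENSPM-CACTA: CACTA
  CMC-ENSPM: CACTA
  PIF: PIF-Harbinger
  HARBINGER: PIF-Harbinger
  BEL: Bel-Pao
  PAO: Bel-Pao
  BEL-PAO: Bel-Pao
  GYPSY: Gypsy
  DIRS1: DIRS
  PENELOPE: Penelope
  ERVL: ERV
  ERV1: ERV
  ALU: tRNA

# Superfamilies recognised without aliasing, keyed by their parent order.
superfamilies:
  LTR: [Gypsy, Copia, Bel-Pao, ERV, Retrovirus]
  DIRS: [DIRS, Ngaro, VIPER]
  PLE: [Penelope]
  LINE: [Jockey, L1, L2, RTE, R2, I, CR1, Rex-Babar]
  SINE: [5S, 7SL, tRNA]
  TIR: [Tc1-Mariner, hAT, CACTA, piggyBac, PIF-Harbinger, Sola, Mutator,
        Merlin, P, Transib, Kolobok, Zisupton, Academ, Ginger, Novosib]
  Helitron: [Helitron]
  Maverick: [Maverick]
  Crypton: [Crypton]
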