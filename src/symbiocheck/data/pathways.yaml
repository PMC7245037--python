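# Biosynthetic pathway definitions for the nutritional-gene census.
#
# Each pathway lists the genes the primary endosymbiont must retain for the
# host-relevant compound. `optional_genes` are genes absent from ALL known
# genomes of the reference endosymbiont clade (their absence carries no
# signal about co-obligacy). `reference` describes the collapsed
# mono-symbiotic reference rows: every panel gene is present except those
# listed under `absent`.
#
# The gene lists here cover the panel exercised by the synthetic community;
# users analysing real data should curate the lists for their clade.
pathways:
  tryptophan:
    compound: Trp
    genes: [trpE, trpG, trpD, trpC, trpA, trpB]
  isoleucine_valine:
    compound: Ile/Val
    genes: [ilvC, ilvD]
  methionine:
    compound: Met
    genes: [metE]
  biotin:
    compound: biotin
    genes: [fabB, bioA, bioB, bioD]
  riboflavin:
    compound: riboflavin
    genes: [ribA, ribD, ribE, ribH]
  lipoate:
    compound: lipoate
    genes: [lipA, lipB]
  hexose_phosphate:
    compound: glucose-phosphate interconversion
    genes: [pgi, pgm]
optional_genes: [pgm]
reference:
  Aph:
    absent: [pgm]
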