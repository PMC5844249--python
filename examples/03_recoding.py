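"""Codon-level consequences of A-to-I edits in coding sequence.

Two classic cases: editing the CAG glutamine codon at its second
position gives CGG (arginine) — the GRIA2-type Q/R recoding — and
editing the TAG stop codon gives TGG (tryptophan), a stop-loss that
extends the protein. Stop gain is impossible: A→G cannot create the U
every stop codon starts with.
"""

from editome.annotate import call_recoding
from editome.io import TranscriptModel


def one_codon_transcript(codon: str):
    """A minimal transcript: ATG + codon + TAA on the plus strand."""
    ref = {"chr1": "NN" + "ATG" + codon + "TAA" + "NN"}
    tx = TranscriptModel("t1", "g1", "G1", "protein_coding", "chr1", "+",
                         exons=[(2, 11)], cds=[(2, 11, 0)])
    return tx, ref


for codon, pos_in_codon in [("CAG", 2), ("TAG", 2), ("CCA", 3)]:
    tx, ref = one_codon_transcript(codon)
    genomic_pos = 5 + pos_in_codon - 1  # codon occupies positions 5..7
    call = call_recoding("chr1", genomic_pos, tx, ref)
    print(f"{codon} edited at codon position {pos_in_codon}: "
          f"{call.codon_before} -> {call.codon_after}  "
          f"({call.aa_change}, {call.consequence})")

# CAG -> CGG is nonsynonymous (Q -> R); TAG -> TGG is a stop-loss that
# appends tryptophan; CCA -> CCG is synonymous (proline either way).
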