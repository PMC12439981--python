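"""Built-in reference sequences.

Mature (initiator-Met-stripped) human histone H4, UniProt P62805.  Positions
throughout the package are 1-based on the mature protein, so ``G4D`` is the
glycine at mature position 4.  The "tail" is the disordered N-terminal
30-residue window used by the repression classifier and the design search.
"""

from .variants import ReferenceHistone

H4_HUMAN_MATURE = (
    "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKVFLENVIRDAV"
    "TYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG"
)

TAIL_LENGTH = 30
H4_TAIL = H4_HUMAN_MATURE[:TAIL_LENGTH]

H4_REFERENCE = ReferenceHistone(family="H4", sequence=H4_HUMAN_MATURE, accession="P62805")
H4_TAIL_REFERENCE = ReferenceHistone(family="H4-tail", sequence=H4_TAIL, accession="P62805")
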