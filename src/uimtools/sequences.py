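"""Peptide sequences with construct numbering.

UIM work is done on expression constructs whose residue numbering follows
the full-length protein (e.g. an ataxin-3 C-terminal construct spanning
residues 306-361, with the third UIM at E336-T350).  All analyses therefore
address residues by construct number, not by 0-based index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class PeptideSequence:
    """A one-letter peptide sequence with contiguous construct numbering.

    Parameters
    ----------
    id : str
        Label of the construct (e.g. ``"AT3_306-361"``).
    residues : str
        One-letter residue string, 20-letter alphabet.
    first_residue_number : int
        Construct number of the first residue (default 1).
    """

    id: str
    residues: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues.upper()) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues in {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> range:
        return range(self.first_residue_number,
                     self.first_residue_number + len(self.residues))

    def index_of(self, residue_number: int) -> int:
        """0-based index of a construct residue number."""
        i = residue_number - self.first_residue_number
        if not 0 <= i < len(self.residues):
            raise IndexError(
                f"residue {residue_number} outside {self.id!r} "
                f"({self.first_residue_number}-{self.residue_numbers[-1]})")
        return i

    def residue(self, residue_number: int) -> str:
        return self.residues[self.index_of(residue_number)]

    def window(self, start: int, stop: int) -> "PeptideSequence":
        """Sub-sequence for construct numbers ``start``..``stop`` inclusive."""
        if stop < start:
            raise ValueError("window stop before start")
        i, j = self.index_of(start), self.index_of(stop)
        return PeptideSequence(f"{self.id}_{start}-{stop}",
                               self.residues[i:j + 1], start)


def demo_uim3_construct() -> PeptideSequence:
    """Synthetic 56-residue UIM3-bearing construct (residues 306-361).

    A synthetic stand-in for an ataxin-3 C-terminal construct: the UIM3
    window E336-T350 carries the canonical features of a disordered UIM
    (N-terminal acidic stretch E336/E337/D338, hydrophobic L340, invariant
    A343 and S347, and the beta-branched V344/T345/T350), embedded in a
    polar, disorder-promoting flanking sequence.  It is generated here, not
    taken from any database.
    """
    flank_n = "SGQEQSPGNKSEPSTGQGSEDPSKSGQGA"  # 306-334 (29 aa)
    uim3 = "G" + "EEDQLRKAVTESQGT" + "G"       # 335, 336-350, 351
    flank_c = "SNSEQPSKSG"                      # 352-361 (10 aa)
    seq = flank_n + uim3 + flank_c
    assert len(seq) == 56
    return PeptideSequence("AT3-like_306-361_synthetic", seq, 306)
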