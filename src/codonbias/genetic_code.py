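"""Standard genetic code with the synonymous-family structure used in codon-usage analysis.

Codon-usage statistics are organised around synonymous families: the groups of
codons translated to the same amino acid. Two families are single-codon
(Met/AUG, Trp/UGG) and therefore carry no usage information; the remaining 59
sense codons (the "analysis codons") are the coordinates of RSCU vectors, CAI
weight tables and correspondence analysis.

Codons are held internally in DNA spelling (T not U); :func:`to_rna` /
:func:`to_dna` convert for reporting, since codon-usage tables are
conventionally printed in RNA spelling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

# canonical codon order: first base slowest, TCAG within each position
_BASE_ORDER = "TCAG"

STOP = "*"


def to_rna(codon: str) -> str:
    """Convert a DNA-spelled codon (or sequence) to RNA spelling."""
    return codon.replace("T", "U").replace("t", "u")


def to_dna(codon: str) -> str:
    """Convert an RNA-spelled codon (or sequence) to DNA spelling."""
    return codon.replace("U", "T").replace("u", "t")


@dataclass
class GeneticCode:
    """A codon -> amino-acid map plus derived synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        All 64 codons (DNA spelling) to one-letter amino acid, ``"*"`` for stop.
    families
        Amino acid -> ordered tuple of synonymous codons (TCAG order).
    degeneracy
        Amino acid -> family size; for the standard code the sizes lie in
        {1, 2, 3, 4, 6}.
    sense_codons
        The 61 non-stop codons, canonical order.
    analysis_codons
        The 59 sense codons excluding the single-codon families (Met, Trp).
    stop_codons
        The 3 stop codons.
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]]
    degeneracy: dict[str, int]
    sense_codons: tuple[str, ...]
    analysis_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    name: str = "standard"
    aa_of: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.aa_of = {c: a for c, a in self.codon_to_aa.items() if a != STOP}

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard nuclear genetic code (NCBI translation table 1)."""
        table = CodonTable.unambiguous_dna_by_id[1]
        codon_to_aa: dict[str, str] = {}
        for codon in ("".join(b) for b in itertools.product(_BASE_ORDER, repeat=3)):
            if codon in table.stop_codons:
                codon_to_aa[codon] = STOP
            else:
                codon_to_aa[codon] = table.forward_table[codon]
        families: dict[str, list[str]] = {}
        for codon, aa in codon_to_aa.items():
            if aa != STOP:
                families.setdefault(aa, []).append(codon)
        fam = {aa: tuple(codons) for aa, codons in families.items()}
        degeneracy = {aa: len(c) for aa, c in fam.items()}
        sense = tuple(c for c in codon_to_aa if codon_to_aa[c] != STOP)
        analysis = tuple(c for c in sense if degeneracy[codon_to_aa[c]] > 1)
        stops = tuple(c for c in codon_to_aa if codon_to_aa[c] == STOP)
        return cls(
            codon_to_aa=codon_to_aa,
            families=fam,
            degeneracy=degeneracy,
            sense_codons=sense,
            analysis_codons=analysis,
            stop_codons=stops,
        )

    def family_of(self, codon: str) -> tuple[str, ...]:
        """The synonymous family containing ``codon`` (DNA spelling)."""
        return self.families[self.codon_to_aa[codon]]


_STANDARD: GeneticCode | None = None


def standard_code() -> GeneticCode:
    """Module-level cached standard genetic code."""
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = GeneticCode.standard()
    return _STANDARD


class InternalStopError(ValueError):
    """Raised when a stop codon occurs before the final codon of a CDS."""

    def __init__(self, position_codon: int):
        self.position_codon = position_codon
        super().__init__(f"internal stop codon at codon position {position_codon}")


def translate(nucleotides: str, code: GeneticCode | None = None) -> str:
    """Translate a validated CDS (DNA spelling) to a one-letter protein string.

    Codons containing ``N`` (or any non-ACGT letter) yield ``X``. A terminal
    stop codon is dropped; an internal stop raises :class:`InternalStopError`
    naming the (0-based) codon position.
    """
    code = code or standard_code()
    if len(nucleotides) % 3 != 0:
        raise ValueError(f"CDS length {len(nucleotides)} is not a multiple of 3")
    n_codons = len(nucleotides) // 3
    residues = []
    for i in range(n_codons):
        codon = nucleotides[3 * i : 3 * i + 3]
        aa = code.codon_to_aa.get(codon)
        if aa is None:
            residues.append("X")
        elif aa == STOP:
            if i == n_codons - 1:
                break
            raise InternalStopError(i)
        else:
            residues.append(aa)
    return "".join(residues)
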