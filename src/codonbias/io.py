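"""Reading, validating and filtering coding sequences.

The entry format is plain multi-record FASTA of nucleotide CDSs. Sequences are
normalised to uppercase DNA (U -> T, IUPAC ambiguity letters -> N) on input.
Filtering follows the usual pre-processing of transcriptome-derived CDS sets:
a minimum-length cut (strictly longer than 300 nt by default, to limit
sampling error in per-gene indices), trimming of any incomplete terminal codon
and of a terminal stop, and rejection of sequences with in-frame internal stop
codons. Rejections are data, not errors: they are returned alongside the
retained set and can be written as a TSV log.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .genetic_code import GeneticCode, standard_code

_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


class FastaParseError(ValueError):
    pass


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T").replace(" ", "").replace("\t", "")
    out = []
    for ch in seq:
        if ch in "ACGT":
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS:
            out.append("N")
        else:
            raise FastaParseError(f"record {record_id!r}: invalid character {ch!r}")
    return "".join(out)


@dataclass
class CodingSequence:
    """One nucleotide CDS record (uppercase DNA, only ACGTN)."""

    id: str
    nucleotides: str

    @property
    def length_nt(self) -> int:
        return len(self.nucleotides)


@dataclass
class SequenceSet:
    """An ordered collection of CDS records with unique ids."""

    records: list[CodingSequence] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, seq_id: str) -> CodingSequence:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)


def read_cds_fasta(path: str | Path, provenance: str | None = None) -> SequenceSet:
    """Read a (possibly line-wrapped) FASTA file of nucleotide CDSs.

    Ids are the first whitespace-delimited token of each header. Sequences are
    uppercased and RNA spelling is mapped to DNA. Text before the first header
    and duplicate ids are hard errors.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
        break
    records = []
    seen: set[str] = set()
    with _io.StringIO(text) as handle:
        for title, seq in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else ""
            if not rec_id:
                raise FastaParseError(f"{path}: empty FASTA header")
            if rec_id in seen:
                raise FastaParseError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            records.append(CodingSequence(id=rec_id, nucleotides=_normalize(seq, rec_id)))
    return SequenceSet(records=records, provenance=provenance or str(path))


def write_cds_fasta(seqset: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write a SequenceSet as wrapped FASTA (deterministic byte layout)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in seqset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.nucleotides), width):
                fh.write(rec.nucleotides[i : i + width] + "\n")


@dataclass
class Rejection:
    """One filtered-out record with the reason it was dropped."""

    id: str
    length_nt: int
    reason: str  # "too_short" | "internal_stop"


def validate_and_filter(
    seqset: SequenceSet,
    min_len_nt: int = 300,
    code: GeneticCode | None = None,
) -> tuple[SequenceSet, list[Rejection]]:
    """Apply the CDS quality filter and return (retained, rejections).

    Retained records are strictly longer than ``min_len_nt`` (measured before
    trimming), trimmed to a whole number of codons, have any terminal stop
    codon removed, and contain no in-frame internal stop. Codons containing N
    are never treated as stops. ``retained + rejected == input`` always.
    """
    code = code or standard_code()
    stops = set(code.stop_codons)
    kept: list[CodingSequence] = []
    rejected: list[Rejection] = []
    for rec in seqset:
        if rec.length_nt <= min_len_nt:
            rejected.append(Rejection(rec.id, rec.length_nt, "too_short"))
            continue
        seq = rec.nucleotides[: (rec.length_nt // 3) * 3]
        if seq[-3:] in stops:
            seq = seq[:-3]
        internal = any(seq[i : i + 3] in stops for i in range(0, len(seq), 3))
        if internal:
            rejected.append(Rejection(rec.id, rec.length_nt, "internal_stop"))
            continue
        kept.append(CodingSequence(id=rec.id, nucleotides=seq))
    return SequenceSet(records=kept, provenance=seqset.provenance), rejected


def write_rejection_log(rejections: list[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlength_nt\treason\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.length_nt}\t{r.reason}\n")
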