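"""Sequence I/O and haplotype handling.

FASTA reading/writing is delegated to Biopython; this module adds the package's
ingestion rules (uppercasing, U→T transliteration, strict IUPAC alphabet,
gap policing) and the haplotype-collapse step that turns a pre-aligned set of
records into the distinct variants with multiplicities.

The toolkit consumes *pre-aligned* FASTA for target haplotypes: multiple
sequence alignment is done upstream with any standard aligner (e.g. MAFFT or
ClustalW) and is deliberately not re-implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .iupac import AlphabetError, validate

logger = logging.getLogger(__name__)

Locus = Literal["16S", "COI", "other"]


class FastaParseError(ValueError):
    """The input could not be parsed as FASTA."""


class AlignmentError(ValueError):
    """Records expected to be aligned have inconsistent lengths."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with its taxon and locus labels.

    ``seq`` is uppercase over the IUPAC codes plus ``'-'``; gaps are only legal
    when the record came from an aligned file.
    """

    id: str
    seq: str
    taxon: str = ""
    locus: Locus = "other"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", validate(self.seq, label=f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class MultipleAlignment:
    """A set of equal-length records, with optional per-record multiplicities."""

    records: list[SequenceRecord]
    counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        length = len(self.records[0].seq)
        for r in self.records:
            if len(r.seq) != length:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.seq)}, expected {length}"
                )
        if not self.counts:
            self.counts = [1] * len(self.records)
        elif len(self.counts) != len(self.records):
            raise ValueError("counts and records differ in length")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, i: int) -> list[str]:
        return [r.seq[i] for r in self.records]


@dataclass
class HaplotypePanel:
    """Target-species haplotypes plus the non-target panel they must differ from."""

    target_haplotypes: MultipleAlignment
    nontarget_seqs: list[SequenceRecord]
    target_taxon: str

    def __post_init__(self) -> None:
        seen = set()
        for r in self.target_haplotypes.records:
            if r.seq in seen:
                raise ValueError(f"duplicate target haplotype {r.id!r}")
            seen.add(r.seq)
        for r in self.nontarget_seqs:
            if r.taxon == self.target_taxon:
                raise ValueError(
                    f"non-target record {r.id!r} carries the target taxon {self.target_taxon!r}"
                )


def read_fasta(
    path: str | Path,
    taxon: str = "",
    locus: Locus = "other",
    aligned: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Sequences are uppercased and ``U`` is transliterated to ``T`` (logged).
    Gap characters are rejected unless ``aligned=True``. Non-IUPAC characters
    raise :class:`~ednamark.iupac.AlphabetError` naming the record and position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0]
        raise FastaParseError(f"{path}: not FASTA — first line {first!r}")
    out: list[SequenceRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if "U" in raw.upper():
            logger.info("record %s: transliterating U->T", rec.id)
        seq = validate(raw, label=f"record {rec.id!r}")
        if not aligned and "-" in seq:
            raise AlphabetError(
                f"record {rec.id!r}: gap character in an unaligned file "
                "(pass aligned=True for aligned FASTA)"
            )
        out.append(SequenceRecord(id=rec.id, seq=seq, taxon=taxon, locus=locus))
    if not out and text.strip():
        raise FastaParseError(f"{path}: no FASTA records parsed")
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA wrapped at *wrap* columns."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def collapse_haplotypes(records: list[SequenceRecord]) -> MultipleAlignment:
    """Collapse equal-length records into distinct haplotypes with counts.

    Grouping is by exact string identity (a gap is a literal character); the
    first-seen record of each haplotype gives its id, and first-seen order is
    retained. The counts sum to the number of input records.
    """
    if not records:
        raise AlignmentError("no records to collapse")
    length = len(records[0].seq)
    index: dict[str, int] = {}
    reps: list[SequenceRecord] = []
    counts: list[int] = []
    for r in records:
        if len(r.seq) != length:
            raise AlignmentError(
                f"record {r.id!r} has length {len(r.seq)}, expected {length}: "
                "haplotype collapse requires pre-aligned input"
            )
        if r.seq in index:
            counts[index[r.seq]] += 1
        else:
            index[r.seq] = len(reps)
            reps.append(r)
            counts.append(1)
    return MultipleAlignment(records=reps, counts=counts)
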