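"""Reference/annotation data model and anticodon-family logic.

A reference panel is a FASTA of small-RNA gene sequences plus a tab-separated
annotation table (``id  category  strand  anticodon_start  amino_acid``).
Sequences are stored genomic plus-strand; ``anticodon_start`` is the 1-based
position of anticodon base 34 in *transcript* orientation, so minus-strand
genes are handled by reverse complementation.  The internal alphabet is RNA
(U); DNA input is normalized on load and written back out as DNA.

The Q-family ("GUN") rule: tRNAs with G at position 34 and U at 35 —
Tyr (GUA), Asp (GUC), His (GUG), Asn (GUU) — are the substrates of the
queuine tRNA ribosyltransferase.  G34 wobble-pairs with both C and U at the
third codon position, so each GUN tRNA decodes the dual synonymous
NAU/NAC codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

CATEGORIES = ("tRNA_cyto", "tRNA_mito", "snoRNA", "rRNA_45S", "other")

_RNA_ALPHABET = set("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

ANNOTATION_COLUMNS = ("id", "category", "strand", "anticodon_start", "amino_acid")


def _normalize(seq: str) -> str:
    """Uppercase and map T→U (internal alphabet is RNA)."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A↔U, C↔G, N↔N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceRecord:
    """One annotated small-RNA gene.

    ``sequence`` is the genomic plus-strand sequence in RNA alphabet;
    ``genome_strand`` says which strand the gene is transcribed from;
    ``anticodon_start`` (tRNA only) is the 1-based transcript position of
    anticodon base 34.
    """

    id: str
    sequence: str
    category: str
    genome_strand: str = "+"
    anticodon_start: int | None = None
    amino_acid: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}; alphabet is A/C/G/U(T)/N")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.id}: unknown category {self.category!r}; allowed: {', '.join(CATEGORIES)}"
            )
        if self.genome_strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.anticodon_start is not None:
            if not 1 <= self.anticodon_start or self.anticodon_start + 2 > len(self.sequence):
                raise ValueError(
                    f"{self.id}: anticodon_start {self.anticodon_start} leaves no room for "
                    f"3 bases in a {len(self.sequence)}-nt sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Anticodon:
    """Three anticodon bases at tRNA positions 34, 35, 36 (5'→3')."""

    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != 3 or set(self.bases) - set("ACGU"):
            raise ValueError(f"anticodon must be exactly 3 RNA bases, got {self.bases!r}")

    def __str__(self) -> str:
        return self.bases


def transcript_of(record: ReferenceRecord) -> str:
    """Gene sequence in transcript (5'→3' RNA) orientation."""
    if record.genome_strand == "-":
        return reverse_complement(record.sequence)
    return record.sequence


def anticodon_of(record: ReferenceRecord) -> Anticodon:
    """Extract the anticodon (transcript positions 34..36) of a tRNA record."""
    if record.anticodon_start is None:
        raise ValueError(f"{record.id}: not a tRNA record (no anticodon_start)")
    i = record.anticodon_start - 1
    return Anticodon(transcript_of(record)[i : i + 3])


def is_q_family(anticodon: Anticodon) -> bool:
    """True iff the anticodon is G34-U35-N36 (the Q-family / GUN rule)."""
    return anticodon.bases[0] == "G" and anticodon.bases[1] == "U"


def codons_decoded(anticodon: Anticodon, wobble: bool = True) -> frozenset[str]:
    """Codons read by an anticodon under antiparallel pairing.

    Codon positions 1 and 2 are the Watson–Crick complements of anticodon
    bases 36 and 35.  At the degenerate third codon position, G34
    wobble-pairs with both C and U (``wobble=True``, the default), which is
    what makes each GUN tRNA decode the dual synonymous NAU and NAC codons;
    with wobble off, or for any non-G base 34, only the Watson–Crick partner
    is returned.
    """
    b34, b35, b36 = anticodon.bases
    first = b36.translate(_COMPLEMENT)
    second = b35.translate(_COMPLEMENT)
    if wobble and b34 == "G":
        thirds = ("C", "U")
    else:
        thirds = (b34.translate(_COMPLEMENT),)
    return frozenset(first + second + t for t in thirds)


def _parse_annotation_row(line: str, lineno: int) -> dict:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != len(ANNOTATION_COLUMNS):
        raise ValueError(f"annotation line {lineno}: expected {len(ANNOTATION_COLUMNS)} columns, got {len(parts)}")
    row = dict(zip(ANNOTATION_COLUMNS, parts))
    if row["category"] not in CATEGORIES:
        raise ValueError(
            f"annotation line {lineno} ({row['id']}): category {row['category']!r} "
            f"not in allowed set {{{', '.join(CATEGORIES)}}}"
        )
    row["anticodon_start"] = None if row["anticodon_start"] == "." else int(row["anticodon_start"])
    row["amino_acid"] = None if row["amino_acid"] == "." else row["amino_acid"]
    return row


def load_references(fasta_source, annotation_table) -> list[ReferenceRecord]:
    """Join a FASTA with its annotation table into :class:`ReferenceRecord` s.

    Both arguments are paths (or open text handles).  Every annotation id
    must exist in the FASTA and vice versa; duplicates are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = _normalize(str(rec.seq))

    rows: list[dict] = []
    seen: set[str] = set()
    if isinstance(annotation_table, (str, Path)):
        handle = open(annotation_table)
        close = True
    else:
        handle, close = annotation_table, False
    try:
        lines = iter(enumerate(handle, start=1))
        header = next(lines, None)
        if header is None or tuple(header[1].rstrip("\n").split("\t")) != ANNOTATION_COLUMNS:
            raise ValueError(f"annotation table must start with header {'	'.join(ANNOTATION_COLUMNS)!r}")
        for lineno, line in lines:
            if not line.strip():
                continue
            row = _parse_annotation_row(line, lineno)
            if row["id"] in seen:
                raise ValueError(f"duplicate annotation id {row['id']!r}")
            if row["id"] not in seqs:
                raise ValueError(f"annotation id {row['id']!r} missing from FASTA")
            seen.add(row["id"])
            rows.append(row)
    finally:
        if close:
            handle.close()

    missing = set(seqs) - seen
    if missing:
        raise ValueError(f"FASTA ids with no annotation row: {sorted(missing)}")

    return [
        ReferenceRecord(
            id=row["id"],
            sequence=seqs[row["id"]],
            category=row["category"],
            genome_strand=row["strand"],
            anticodon_start=row["anticodon_start"],
            amino_acid=row["amino_acid"],
        )
        for row in rows
    ]


def write_references(records: Iterable[ReferenceRecord], fasta_path, annotation_path) -> None:
    """Write a panel back out as DNA FASTA + TSV annotation (round-trips load)."""
    records = list(records)
    with open(fasta_path, "w") as fa:
        for r in records:
            fa.write(f">{r.id}\n{r.sequence.replace('U', 'T')}\n")
    with open(annotation_path, "w") as tsv:
        tsv.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in records:
            tsv.write(
                "\t".join(
                    [
                        r.id,
                        r.category,
                        r.genome_strand,
                        "." if r.anticodon_start is None else str(r.anticodon_start),
                        "." if r.amino_acid is None else r.amino_acid,
                    ]
                )
                + "\n"
            )
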