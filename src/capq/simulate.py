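"""Synthetic read generator emulating the covalent capture-release assay.

The assay stalls the queuine tRNA ribosyltransferase on its RNA substrate
with 9-deazaguanine, purifies the covalent enzyme–RNA intermediate and
releases the RNA with NaOH, leaving an abasic site at anticodon position 34.
During library preparation HIV reverse transcriptase either reads through
the abasic site — in the majority of cases inserting thymidine opposite it
(the diagnostic G→T transversion in read space) — or terminates in its
vicinity, which biases coverage toward the 3' side of the site.  NaOH can
additionally cleave the backbone at the abasic site, splitting the molecule
into 5' and 3' fragments.

``simulate_capture`` emits single-end DNA reads (FASTQ, constant Phred-33
qualities) drawn from a mixed small-RNA pool under that generative model,
together with a per-read/per-reference truth table so every downstream
stage can be checked against known ground truth.  ``build_reference_panel``
fabricates a small annotated gene panel (substrate GUN tRNAs, non-GUN
tRNAs, snoRNAs, a 45S pre-rRNA fragment) plus a contaminant FASTA.

Default RT-outcome split (read-through with T 0.6, read-through with another
base 0.1, termination 0.3) encodes "majority" thymidine incorporation and a
"significant proportion" of terminations while keeping the ≥30% transversion
filter attainable; all three are ordinary config fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from capq.references import ReferenceRecord, anticodon_of, is_q_family, transcript_of

READ_OUTCOMES = ("readthrough_T", "readthrough_other", "terminated", "cleaved_5p", "cleaved_3p", "none")

_DNA = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Generative parameters of one simulated capture-release run.

    ``abundances`` maps reference id → expected molecule count (Poisson
    mean).  ``captured_fraction`` maps reference id → probability that a
    molecule of that reference is a captured enzyme substrate (must be 0
    for anything that is not an annotated GUN tRNA).  The three RT-outcome
    probabilities must sum to 1.
    """

    abundances: dict[str, float]
    captured_fraction: dict[str, float] = field(default_factory=dict)
    p_readthrough_T: float = 0.6
    p_readthrough_other: float = 0.1
    p_terminate: float = 0.3
    p_backbone_cleave: float = 0.0
    seq_error_rate: float = 0.005
    read_length: int = 65
    min_fragment_length: int = 16
    contaminant_fraction: float = 0.0
    cca_tail: bool = True
    truncation_jitter: int = 0
    quality_char: str = "I"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_readthrough_T": self.p_readthrough_T,
            "p_readthrough_other": self.p_readthrough_other,
            "p_terminate": self.p_terminate,
            "p_backbone_cleave": self.p_backbone_cleave,
            "seq_error_rate": self.seq_error_rate,
            "contaminant_fraction": self.contaminant_fraction,
            **{f"captured_fraction[{k}]": v for k, v in self.captured_fraction.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        total = self.p_readthrough_T + self.p_readthrough_other + self.p_terminate
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"RT outcome probabilities sum to {total}, must sum to 1")
        if self.read_length < self.min_fragment_length:
            raise ValueError("read_length below min_fragment_length")


@dataclass
class TruthTable:
    """Ground truth of a simulated run.

    ``reads`` has one row per emitted read (read_id, ref_id, start, end in
    transcript coordinates, captured, outcome, contaminant); ``references``
    aggregates true molecule and captured-molecule counts per reference.
    """

    reads: pd.DataFrame
    references: pd.DataFrame

    def to_tsv(self, reads_path, references_path) -> None:
        self.reads.to_csv(reads_path, sep="\t", index=False)
        self.references.to_csv(references_path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def build_reference_panel(
    n_substrate_trna: int,
    n_nonsubstrate_trna: int,
    n_snorna: int,
    n_rrna: int,
    seed: int,
    n_mito_trna: int = 0,
    minus_strand_fraction: float = 0.25,
) -> tuple[list[ReferenceRecord], list[tuple[str, str]]]:
    """Fabricate an annotated small-RNA panel and a contaminant set.

    Substrate tRNAs carry a GUN anticodon (G34, U35) at the annotated
    position; non-substrate tRNAs a non-GUN anticodon; snoRNA/rRNA entries
    are unstructured fragments in the 70–200 nt range.  A fixed fraction of
    genes is placed on the genomic minus strand (the stored sequence is the
    plus-strand image) so the C→A minus-strand signature is exercised.
    Deterministic under ``seed``.

    Returns ``(references, contaminants)`` where contaminants is a list of
    ``(id, DNA sequence)`` pairs emulating the foreign (E. coli-like)
    reads depleted before analysis.
    """
    rng = np.random.default_rng(seed)
    refs: list[ReferenceRecord] = []

    gun_aa = [("Asp", "GUC"), ("Tyr", "GUA"), ("His", "GUG"), ("Asn", "GUU")]
    non_gun_aa = [("Arg", "CCU"), ("Leu", "CAA"), ("Gly", "GCC"), ("Lys", "UUU")]

    def make_trna(name: str, anticodon: str, aa: str, category: str) -> ReferenceRecord:
        length = int(rng.integers(60, 91))
        start = int(rng.integers(30, 38))  # anticodon sits mid-molecule
        seq = list(_random_seq(rng, length))
        seq[start - 2] = "U"  # U33, part of the recognition motif
        seq[start - 1 : start + 2] = list(anticodon)
        transcript = "".join(seq)
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        from capq.references import reverse_complement

        stored = reverse_complement(transcript) if strand == "-" else transcript
        return ReferenceRecord(
            id=name, sequence=stored, category=category,
            genome_strand=strand, anticodon_start=start, amino_acid=aa,
        )

    for i in range(n_substrate_trna):
        aa, ac = gun_aa[i % len(gun_aa)]
        refs.append(make_trna(f"tRNA-{aa}-{ac}-{i + 1}", ac, aa, "tRNA_cyto"))
    for i in range(n_mito_trna):
        aa, ac = gun_aa[i % len(gun_aa)]
        refs.append(make_trna(f"mt-tRNA-{aa}-{ac}-{i + 1}", ac, aa, "tRNA_mito"))
    for i in range(n_nonsubstrate_trna):
        aa, ac = non_gun_aa[i % len(non_gun_aa)]
        refs.append(make_trna(f"tRNA-{aa}-{ac}-{i + 1}", ac, aa, "tRNA_cyto"))
    for i in range(n_snorna):
        length = int(rng.integers(70, 201))
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        refs.append(
            ReferenceRecord(
                id=f"SNORD-sim-{i + 1}", sequence=_random_seq(rng, length),
                category="snoRNA", genome_strand=strand,
            )
        )
    for i in range(n_rrna):
        length = int(rng.integers(120, 201))
        refs.append(
            ReferenceRecord(
                id=f"RNA45S-frag-{i + 1}", sequence=_random_seq(rng, length),
                category="rRNA_45S", genome_strand="+",
            )
        )

    contaminants = [
        (f"contam-{i + 1}", _random_seq(rng, int(rng.integers(150, 400))).replace("U", "T"))
        for i in range(4)
    ]
    return refs, contaminants


def _apply_errors(rng: np.random.Generator, read: np.ndarray, rate: float) -> None:
    """In-place uniform substitution errors on a byte array of ACGT."""
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(read.size) < rate)[0]
    for i in hits:
        choices = _DNA[_DNA != read[i]]
        read[i] = rng.choice(choices)


def simulate_capture(
    references: list[ReferenceRecord],
    config: SimConfig,
    contaminants: list[tuple[str, str]] | None = None,
) -> tuple[list[tuple[str, str, str]], TruthTable]:
    """Emit reads from a capture-release run under the abasic-site model.

    Returns ``(reads, truth)`` where each read is ``(read_id, sequence,
    quality)`` in DNA alphabet.  Per captured molecule, position 34 is
    abasic: the read either carries T there (``p_readthrough_T``), carries
    a random non-T base (``p_readthrough_other``) or is truncated so it
    starts 3' of the site (``p_terminate``); with ``p_backbone_cleave`` the
    molecule is emitted as separate 5'/3' fragments instead.  CCA is
    appended to mature tRNA molecules when ``cca_tail``.  With probability
    ``contaminant_fraction`` a molecule is replaced by a contaminant read.
    Byte-identical output under a fixed seed.
    """
    config.validate()
    by_id = {r.id: r for r in references}
    for ref_id, frac in config.captured_fraction.items():
        if frac <= 0:
            continue
        ref = by_id.get(ref_id)
        if ref is None:
            raise ValueError(f"captured_fraction set for unknown reference {ref_id!r}")
        if ref.anticodon_start is None:
            raise ValueError(f"captured_fraction > 0 on non-tRNA reference {ref_id!r}")
        if not is_q_family(anticodon_of(ref)):
            raise ValueError(f"captured_fraction > 0 on non-GUN reference {ref_id!r}")
    if config.contaminant_fraction > 0 and not contaminants:
        raise ValueError("contaminant_fraction > 0 but no contaminant sequences supplied")

    rng = np.random.default_rng(config.seed)
    reads: list[tuple[str, str, str]] = []
    rows: list[tuple] = []
    mol_counts: dict[str, int] = {r.id: 0 for r in references}
    cap_counts: dict[str, int] = {r.id: 0 for r in references}
    n_read = 0

    def emit(seq_rna: str, ref_id: str, start: int, end: int, captured: bool, outcome: str, contaminant: bool):
        nonlocal n_read
        if len(seq_rna) < config.min_fragment_length:
            return
        arr = np.frombuffer(seq_rna.replace("U", "T").encode(), dtype="S1").copy()
        _apply_errors(rng, arr, config.seq_error_rate)
        seq = arr.tobytes().decode()
        rid = f"read{n_read:07d}"
        n_read += 1
        reads.append((rid, seq, config.quality_char * len(seq)))
        rows.append((rid, ref_id, start, end, captured, outcome, contaminant))

    for ref in references:
        mean = config.abundances.get(ref.id, 0.0)
        if mean <= 0:
            continue
        n_mol = int(rng.poisson(mean))
        mol_counts[ref.id] = n_mol
        cap_frac = config.captured_fraction.get(ref.id, 0.0)
        transcript = transcript_of(ref)
        tail = "CCA" if (config.cca_tail and ref.category in ("tRNA_cyto", "tRNA_mito")) else ""
        abasic = None if ref.anticodon_start is None else ref.anticodon_start - 1
        L = config.read_length

        for _ in range(n_mol):
            if contaminants and rng.random() < config.contaminant_fraction:
                cid, cseq = contaminants[int(rng.integers(len(contaminants)))]
                clen = min(L, len(cseq))
                cstart = int(rng.integers(0, len(cseq) - clen + 1))
                emit(cseq[cstart : cstart + clen].replace("T", "U"), cid, cstart, cstart + clen, False, "none", True)
                continue

            captured = cap_frac > 0 and rng.random() < cap_frac
            if not captured:
                mol = transcript + tail
                emit(mol[:L], ref.id, 0, min(L, len(mol)), False, "none", False)
                continue

            cap_counts[ref.id] += 1
            if rng.random() < config.p_backbone_cleave:
                # NaOH breaks the backbone: 5' and 3' fragments, abasic base lost
                five = transcript[:abasic]
                three = transcript[abasic + 1 :] + tail
                emit(five[:L], ref.id, 0, min(L, abasic), True, "cleaved_5p", False)
                emit(three[:L], ref.id, abasic + 1, abasic + 1 + min(L, len(three)), True, "cleaved_3p", False)
                continue

            u = rng.random()
            if u < config.p_readthrough_T:
                mol = transcript[:abasic] + "U" + transcript[abasic + 1 :] + tail  # U → T in read space
                emit(mol[:L], ref.id, 0, min(L, len(mol)), True, "readthrough_T", False)
            elif u < config.p_readthrough_T + config.p_readthrough_other:
                ref_base = transcript[abasic]
                other = rng.choice([b for b in "ACG" if b != ref_base.replace("U", "T")])
                mol = transcript[:abasic] + str(other) + transcript[abasic + 1 :] + tail
                emit(mol[:L], ref.id, 0, min(L, len(mol)), True, "readthrough_other", False)
            else:
                start = abasic + 1
                if config.truncation_jitter:
                    start += int(rng.integers(-config.truncation_jitter, config.truncation_jitter + 1))
                    start = max(0, min(start, len(transcript) - 1))
                mol = transcript[start:] + tail
                emit(mol[:L], ref.id, start, start + min(L, len(mol)), True, "terminated", False)

    truth_reads = pd.DataFrame(
        rows, columns=["read_id", "ref_id", "start", "end", "captured", "outcome", "contaminant"]
    )
    truth_refs = pd.DataFrame(
        {
            "ref_id": [r.id for r in references],
            "category": [r.category for r in references],
            "molecules": [mol_counts[r.id] for r in references],
            "captured": [cap_counts[r.id] for r in references],
            "reads": [
                int((truth_reads["ref_id"] == r.id).sum()) if len(truth_reads) else 0
                for r in references
            ],
        }
    )
    return reads, TruthTable(truth_reads, truth_refs)


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality) triples as Phred-33 FASTQ."""
    with open(path, "w") as fq:
        for rid, seq, qual in reads:
            fq.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read Phred-33 FASTQ into (id, sequence, quality) triples."""
    out = []
    with open(path) as fq:
        while True:
            h = fq.readline()
            if not h:
                break
            seq = fq.readline().strip()
            fq.readline()
            qual = fq.readline().strip()
            out.append((h.strip()[1:].split()[0], seq, qual))
    return out


def default_config(
    references: list[ReferenceRecord],
    total_molecules: int = 20000,
    captured_fraction: float = 0.85,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A run configuration with equal abundances and capture on every GUN tRNA."""
    n = max(len(references), 1)
    abundances = {r.id: total_molecules / n for r in references}
    captured = {}
    for r in references:
        if r.anticodon_start is not None and is_q_family(anticodon_of(r)):
            captured[r.id] = captured_fraction
    cfg = SimConfig(abundances=abundances, captured_fraction=captured, seed=seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown SimConfig field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
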