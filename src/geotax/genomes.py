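"""Sequence I/O, per-genome descriptive statistics and a minimal ORF caller.

Real-data users supply annotator-produced proteomes; the ORF caller exists so
synthetic genomes are self-contained and is explicitly a stand-in, not an
annotator (no RBS model, no partial genes at contig ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes (uppercase); proteins: 20 standard residues plus X.
NT_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

STOP_CODONS_TABLE11 = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class GenomeRecord:
    """A genome assembly: ordered nucleotide contigs plus provenance."""

    genome_id: str
    contigs: list[str]
    source: str = ""
    headers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be nonempty")
        if not self.contigs or any(len(c) < 1 for c in self.contigs):
            raise ValueError(f"{self.genome_id}: every contig must be nonempty")

    @property
    def size_bp(self) -> int:
        return sum(len(c) for c in self.contigs)

    def sequence(self) -> str:
        """All contigs joined (no separator); convenience for single-contig use."""
        return "".join(self.contigs)


@dataclass
class ProteomeRecord:
    """A predicted proteome: mapping of stable protein ids to sequences."""

    genome_id: str
    proteins: dict[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be nonempty")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    size_bp: int
    gc_percent: float
    n_contigs: int


def _validate(seq: str, alphabet: frozenset, record_id: str, path) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(
            f"record {record_id!r} in {path}: characters {sorted(bad)} outside "
            f"the {'nucleotide' if alphabet is NT_ALPHABET else 'protein'} alphabet"
        )


def read_fasta(
    path: str | Path, alphabet: Literal["nucleotide", "protein"] = "nucleotide"
) -> GenomeRecord | ProteomeRecord:
    """Read a FASTA file into a GenomeRecord (nucleotide) or ProteomeRecord.

    Record ids are the first whitespace-delimited header token; sequences are
    uppercased and gap characters stripped.  The file's stem names the
    genome/proteome.  Raises ``ValueError`` on empty files, duplicate ids or
    characters outside the alphabet (the offending record is named).
    """
    path = Path(path)
    allowed = NT_ALPHABET if alphabet == "nucleotide" else AA_ALPHABET
    ids: list[str] = []
    seqs: list[str] = []
    headers: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        _validate(seq, allowed, rec.id, path)
        if rec.id in ids:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        ids.append(rec.id)
        seqs.append(seq)
        headers.append(rec.description)
    if not ids:
        raise ValueError(f"empty FASTA file: {path}")
    name = path.stem
    if alphabet == "nucleotide":
        return GenomeRecord(genome_id=name, contigs=seqs, source=str(path), headers=headers)
    return ProteomeRecord(genome_id=name, proteins=dict(zip(ids, seqs)), source=str(path))


def write_fasta(
    records: GenomeRecord | ProteomeRecord | Iterable[tuple[str, str]],
    path: str | Path,
    line_width: int = 60,
) -> Path:
    """Write sequences to FASTA; round-trips exactly through :func:`read_fasta`."""
    path = Path(path)
    if isinstance(records, GenomeRecord):
        items = [
            (records.headers[i] if i < len(records.headers) else f"{records.genome_id}_contig{i + 1}", c)
            for i, c in enumerate(records.contigs)
        ]
    elif isinstance(records, ProteomeRecord):
        items = list(records.proteins.items())
    else:
        items = list(records)
    if not items:
        raise ValueError("refusing to write an empty FASTA file")
    seq_records = [
        SeqRecord(Seq(seq), id=name.split()[0], description=name) for name, seq in items
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seq_records)
    return path


def genome_stats(genome: GenomeRecord) -> GenomeStats:
    """Size, contig count and G+C content of an assembly.

    G+C is 100*(G+C)/(A+C+G+T) over all contigs: ambiguous bases are excluded
    from numerator and denominator (so N-padding cannot shift the value), while
    ``size_bp`` counts every base including N.  Reported to one decimal, the
    precision genome tables conventionally use.
    """
    gc = 0
    unambiguous = 0
    for contig in genome.contigs:
        gc += contig.count("G") + contig.count("C")
        unambiguous += gc_denominator(contig)
    if unambiguous == 0:
        raise ValueError(f"{genome.genome_id}: no unambiguous bases, G+C undefined")
    return GenomeStats(
        genome_id=genome.genome_id,
        size_bp=genome.size_bp,
        gc_percent=round(100.0 * gc / unambiguous, 1),
        n_contigs=len(genome.contigs),
    )


def gc_denominator(contig: str) -> int:
    return sum(contig.count(b) for b in "ACGT")


def stats_table(genomes: Iterable[GenomeRecord]):
    """GenomeStats for a collection as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [genome_stats(g).__dict__ for g in genomes]
    return pd.DataFrame(rows, columns=["genome_id", "size_bp", "gc_percent", "n_contigs"])


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs(
    genome: GenomeRecord, min_len_nt: int = 300, translation_table: int = 11
) -> ProteomeRecord:
    """Naive six-frame ORF caller: ATG to the next in-frame stop.

    ``min_len_nt`` counts nucleotides from the ATG through the stop codon
    inclusive.  Within one reading frame, nested starts sharing a stop are
    resolved by keeping the longest ORF (the first ATG after the previous
    stop).  ORFs without an in-frame stop are dropped.  Proteins are returned
    without the stop, ordered by (contig, strand, start); ids encode contig
    index, strand and 1-based start so they are stable across runs.
    """
    if min_len_nt < 30 or min_len_nt % 3:
        raise ValueError("min_len_nt must be >= 30 and a multiple of 3")
    found: list[tuple[int, int, int, str, str]] = []
    for ci, contig in enumerate(genome.contigs):
        for strand, seq in (("+", contig), ("-", _revcomp(contig))):
            n = len(seq)
            for frame in range(3):
                start: int | None = None
                for pos in range(frame, n - 2, 3):
                    codon = seq[pos : pos + 3]
                    if codon in STOP_CODONS_TABLE11:
                        if start is not None and pos + 3 - start >= min_len_nt:
                            orf = seq[start : pos + 3]
                            # report coordinates on the forward strand, 1-based
                            fwd_start = start + 1 if strand == "+" else n - (pos + 3) + 1
                            pid = f"{genome.genome_id}|c{ci}{strand}{fwd_start}"
                            aa = str(Seq(orf).translate(table=translation_table))
                            found.append(
                                (ci, 0 if strand == "+" else 1, fwd_start, pid, aa[:-1].replace("*", "X"))
                            )
                        start = None
                    elif codon == "ATG" and start is None:
                        start = pos
    found.sort(key=lambda t: t[:3])
    proteins = {pid: aa for *_, pid, aa in found}
    return ProteomeRecord(genome_id=genome.genome_id, proteins=proteins, source="find_orfs")
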