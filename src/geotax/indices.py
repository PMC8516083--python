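"""The four similarity indices genus/species demarcation rests on.

* ANIb — fragment-based average nucleotide identity: the query genome is
  chopped into ~1 kb pieces, each mapped into the subject genome (both
  strands), and identity is averaged over fragments passing the standard
  30% identity / 70% coverage filters.
* AAI — mean identity of reciprocal best-hit (RBH) protein pairs.
* POCP — percentage of conserved proteins, 100*(C1+C2)/(T1+T2) where C are
  proteins with a qualifying hit in the other proteome and T total counts.
* SSU — pairwise 16S rRNA gene identity from a global alignment.

Indices with no passing units are reported as undefined (``value_percent``
None), never as 0: a bad input must not masquerade as maximal divergence.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Literal

from Bio.Seq import Seq

from .align import align_global_nt, align_local, local_score, map_fragment_best_strand
from .genomes import GenomeRecord, ProteomeRecord

IndexKind = Literal["ANI", "AAI", "POCP", "SSU"]


@dataclass(frozen=True)
class IndexValue:
    """One pairwise index value with its unit bookkeeping.

    ``n_units`` counts the contributing units: retained fragments (ANI), RBH
    pairs (AAI), conserved proteins C1+C2 (POCP) or aligned columns (SSU).
    """

    genome_a: str
    genome_b: str
    index_kind: IndexKind
    value_percent: float | None
    n_units: int
    direction: Literal["a_to_b", "b_to_a", "symmetric"] = "symmetric"

    def __post_init__(self) -> None:
        if self.value_percent is not None and not (0.0 <= self.value_percent <= 100.0):
            raise ValueError("value_percent outside [0, 100]")

    @property
    def defined(self) -> bool:
        return self.value_percent is not None


# ---------------------------------------------------------------------------
# protein search: k-mer prefilter + Smith-Waterman on the shortlist
# ---------------------------------------------------------------------------

_KMER = 4
_MAX_CANDIDATES = 8


class ProteomeIndex:
    """K-mer shortlist index over a proteome for best-hit searches.

    Candidate subjects are ranked by shared 4-mer count and only the top few
    are aligned by Smith-Waterman (BLOSUM62, affine 11/1), which keeps
    all-vs-all proteome searches tractable without an external search tool.
    The shortlist is a heuristic in the same spirit as word seeding in
    production search tools; the alignment itself is exact DP.
    """

    def __init__(self, proteome: ProteomeRecord, k: int = _KMER):
        self.proteome = proteome
        self.k = k
        self.total_residues = sum(len(s) for s in proteome.proteins.values())
        self._kmers: dict[str, list[str]] = defaultdict(list)
        for pid in sorted(proteome.proteins):
            seq = proteome.proteins[pid]
            seen = set()
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if w not in seen:
                    seen.add(w)
                    self._kmers[w].append(pid)

    def candidates(self, query: str, max_candidates: int = _MAX_CANDIDATES) -> list[str]:
        counts: dict[str, int] = defaultdict(int)
        seen = set()
        for i in range(len(query) - self.k + 1):
            w = query[i : i + self.k]
            if w in seen:
                continue
            seen.add(w)
            for pid in self._kmers.get(w, ()):
                counts[pid] += 1
        ranked = sorted(counts, key=lambda pid: (-counts[pid], pid))
        return ranked[:max_candidates]

    def best_hit(self, query_id: str, query: str):
        """Highest-scoring subject for a query (ties: lexicographic id)."""
        best = None
        best_key = None
        for pid in self.candidates(query):
            score = local_score(query, self.proteome.proteins[pid])
            key = (-score, pid)
            if best_key is None or key < best_key:
                best_key = key
                best = pid
        if best is None:
            return None
        hits = align_local(
            query, self.proteome.proteins[best], query_id=query_id, subject_id=best
        )
        return hits[0] if hits else None


def _best_hits(qry: ProteomeRecord, idx: ProteomeIndex):
    out = {}
    for pid in sorted(qry.proteins):
        hit = idx.best_hit(pid, qry.proteins[pid])
        if hit is not None:
            out[pid] = hit
    return out


def compute_aai(
    prot_a: ProteomeRecord,
    prot_b: ProteomeRecord,
    min_identity: float = 30.0,
    min_cov: float = 70.0,
) -> IndexValue:
    """Average amino-acid identity over reciprocal best-hit pairs.

    A pair is kept when each protein is the other's best hit and the
    alignment reaches ``min_identity`` with coverage ``min_cov`` of the
    shorter sequence.  Undefined (None) when no RBH pair passes.
    """
    if not prot_a.proteins or not prot_b.proteins:
        raise ValueError("both proteomes must be nonempty")
    idx_b = ProteomeIndex(prot_b)
    idx_a = ProteomeIndex(prot_a)
    fwd = _best_hits(prot_a, idx_b)
    rev = _best_hits(prot_b, idx_a)
    identities = []
    for pid_a, hit in sorted(fwd.items()):
        pid_b = hit.subject_id
        back = rev.get(pid_b)
        if back is None or back.subject_id != pid_a:
            continue
        shorter = min(len(prot_a.proteins[pid_a]), len(prot_b.proteins[pid_b]))
        # aligned residues of the shorter sequence, from the forward hit
        cov = 100.0 * hit.aln_len / shorter if shorter else 0.0
        cov = min(cov, 100.0)
        if hit.identity_percent >= min_identity and cov >= min_cov:
            identities.append((hit.identity_percent + back.identity_percent) / 2.0)
    if not identities:
        return IndexValue(prot_a.genome_id, prot_b.genome_id, "AAI", None, 0)
    return IndexValue(
        prot_a.genome_id,
        prot_b.genome_id,
        "AAI",
        sum(identities) / len(identities),
        len(identities),
    )


def compute_pocp(
    prot_a: ProteomeRecord,
    prot_b: ProteomeRecord,
    max_evalue: float = 1e-5,
    min_identity: float = 40.0,
    min_query_cov: float = 50.0,
) -> IndexValue:
    """Percentage of conserved proteins, 100*(C1+C2)/(T1+T2).

    C1 counts proteins of A whose best hit in B has E-value below
    ``max_evalue``, identity above ``min_identity`` and an aligned region
    longer than ``min_query_cov`` of the query length; C2 symmetrically.
    The E-value search space is query length times total subject residues.
    0 is a valid POCP, so the value is always defined.
    """
    if not prot_a.proteins or not prot_b.proteins:
        raise ValueError("both proteomes must be nonempty")

    def conserved(qry: ProteomeRecord, idx: ProteomeIndex) -> int:
        n = 0
        for pid in sorted(qry.proteins):
            hit = idx.best_hit(pid, qry.proteins[pid])
            if hit is None:
                continue
            qlen = len(qry.proteins[pid])
            evalue = hit.evalue / len(idx.proteome.proteins[hit.subject_id]) * idx.total_residues
            qcov = 100.0 * hit.aln_len / qlen
            if evalue < max_evalue and hit.identity_percent > min_identity and qcov > min_query_cov:
                n += 1
        return n

    c1 = conserved(prot_a, ProteomeIndex(prot_b))
    c2 = conserved(prot_b, ProteomeIndex(prot_a))
    t1, t2 = len(prot_a.proteins), len(prot_b.proteins)
    return IndexValue(
        prot_a.genome_id,
        prot_b.genome_id,
        "POCP",
        100.0 * (c1 + c2) / (t1 + t2),
        c1 + c2,
    )


# ---------------------------------------------------------------------------
# nucleotide indices
# ---------------------------------------------------------------------------


def _fragments(genome: GenomeRecord, fragment_len: int, min_tail: int = 100) -> list[str]:
    frags = []
    for contig in genome.contigs:
        for i in range(0, len(contig), fragment_len):
            piece = contig[i : i + fragment_len]
            if len(piece) == fragment_len or len(piece) >= min_tail:
                frags.append(piece)
    return frags


def _directional_ani(
    query: GenomeRecord,
    subject_seq: str,
    fragment_len: int,
    min_identity: float,
    min_frag_cov: float,
) -> tuple[float | None, int]:
    identities = []
    for frag in _fragments(query, fragment_len):
        best = map_fragment_best_strand(
            frag, str(Seq(frag).reverse_complement()), subject_seq
        )
        if best is None:
            continue
        identity, coverage, _ = best
        if identity >= min_identity and coverage >= min_frag_cov:
            identities.append(identity)
    if not identities:
        return None, 0
    return sum(identities) / len(identities), len(identities)


def compute_anib(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    fragment_len: int = 1020,
    min_identity: float = 30.0,
    min_frag_cov: float = 70.0,
) -> IndexValue:
    """Fragment-based average nucleotide identity (ANIb convention).

    Each genome is chopped into consecutive ``fragment_len`` pieces (a final
    short piece is kept if >= 100 bp), every fragment is mapped into the other
    genome on both strands, and fragments are retained when the best placement
    reaches ``min_identity`` over at least ``min_frag_cov`` of the fragment.
    The reported value is the mean of the two directional means; ``n_units``
    is the total retained fragment count.
    """
    if genome_a.size_bp < fragment_len or genome_b.size_bp < fragment_len:
        raise ValueError("both genomes must be at least one fragment long")
    seq_a = "N".join(genome_a.contigs)
    seq_b = "N".join(genome_b.contigs)
    ab, n_ab = _directional_ani(genome_a, seq_b, fragment_len, min_identity, min_frag_cov)
    ba, n_ba = _directional_ani(genome_b, seq_a, fragment_len, min_identity, min_frag_cov)
    values = [v for v in (ab, ba) if v is not None]
    if not values:
        return IndexValue(genome_a.genome_id, genome_b.genome_id, "ANI", None, 0)
    return IndexValue(
        genome_a.genome_id,
        genome_b.genome_id,
        "ANI",
        sum(values) / len(values),
        n_ab + n_ba,
    )


def compute_16s_identity(
    ssu_a: str, ssu_b: str, id_a: str = "a", id_b: str = "b"
) -> IndexValue:
    """Pairwise 16S rRNA gene identity from a global alignment.

    Identity is taken over aligned columns excluding terminal gaps.  Warns
    (but proceeds) below 1,200 nt, the conventional near-full-length bar.
    """
    if not ssu_a or not ssu_b:
        raise ValueError("empty 16S sequence")
    if min(len(ssu_a), len(ssu_b)) < 1200:
        warnings.warn("16S sequence shorter than 1,200 nt; identity may be unstable")
    hit = align_global_nt(ssu_a, ssu_b, query_id=id_a, subject_id=id_b)
    return IndexValue(id_a, id_b, "SSU", hit.identity_percent, hit.aln_len)
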