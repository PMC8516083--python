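"""Pairwise alignment primitives shared by all similarity indices.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment with affine
gaps run on Bio.Align.PairwiseAligner; hit statistics follow the
Karlin-Altschul model with parameters fixed per scoring scheme, since the
services whose output these indices emulate filter hits by E-value.  The
Kimura two-parameter distance used for SSU trees lives here too.

A backend seam (`map_fragment`) lets genome-scale fragment searches run on
edlib's bit-vector aligner; the quadratic DP remains the reference
implementation and is what the local/global operations use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

#: Gapped Karlin-Altschul parameters (lambda, K) per scoring scheme.  Values
#: are the published ones used by BLAST for BLOSUM62 with affine(11,1) and for
#: match/mismatch +1/-2 with affine(5,2).
KARLIN_ALTSCHUL = {
    ("blosum62", 11, 1): (0.267, 0.041),
    ("nt+1-2", 5, 2): (1.28, 0.46),
}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_NT = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise alignment: identity, span, coverage and significance.

    ``identity_percent`` is matched columns / aligned columns * 100, where the
    column set excludes terminal gaps in global mode and is the local
    alignment span in local mode (the two dominant conventions).
    """

    query_id: str
    subject_id: str
    identity_percent: float
    aln_len: int
    query_cov_percent: float
    score: float
    evalue: float
    query_start: int = 0  # 0-based on the query
    subject_start: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_percent <= 100.0):
            raise ValueError("identity_percent outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@lru_cache(maxsize=8)
def _global_nt_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # terminal gaps are not penalised: identity is taken over the overlap
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


@lru_cache(maxsize=8)
def _local_aligner(scoring: str, gap_open: float, gap_extend: float, alphabet: str):
    import os

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if alphabet == "protein":
        if os.path.isfile(scoring):  # NCBI-format matrix file
            aligner.substitution_matrix = substitution_matrices.read(scoring)
        else:
            aligner.substitution_matrix = substitution_matrices.load(scoring.upper())
    elif scoring == "nt+1-2":
        aligner.match_score = 1
        aligner.mismatch_score = -2
    else:
        raise ValueError(f"unknown scoring scheme {scoring!r} for alphabet {alphabet!r}")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _column_stats(alignment) -> tuple[int, int, int]:
    """(matches, aligned columns incl. internal gaps, query residues aligned)."""
    counts = alignment.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    q = alignment.aligned[1]
    query_res = int(sum(e - s for s, e in q))
    return matches, columns, query_res


def align_global_nt(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
    query_id: str = "a",
    subject_id: str = "b",
) -> AlignmentHit:
    """Global nucleotide alignment with affine gaps and free terminal gaps.

    Identity is computed over aligned columns after excluding terminal gap
    columns, the convention pairwise SSU identity services use.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _global_nt_aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(seq_b, seq_a)[0]  # target, query
    matches, columns, query_res = _column_stats(alignment)
    lam, k = KARLIN_ALTSCHUL[("nt+1-2", 5, 2)]
    evalue = k * len(seq_a) * len(seq_b) * math.exp(-lam * max(alignment.score, 0.0))
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_percent=100.0 * matches / columns if columns else 0.0,
        aln_len=max(columns, 1),
        query_cov_percent=100.0 * query_res / len(seq_a),
        score=float(alignment.score),
        evalue=evalue,
    )


def align_local(
    seq_a: str,
    seq_b: str,
    scoring: str = "blosum62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    alphabet: str = "protein",
    query_id: str = "a",
    subject_id: str = "b",
    min_score: float = 0.0,
) -> list[AlignmentHit]:
    """Best local alignment under a substitution matrix with affine gaps.

    Returns a singleton list (the optimal alignment) or an empty list when no
    alignment scores above ``min_score``.  E-values follow Karlin-Altschul
    statistics with parameters fixed per scoring scheme.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = _local_aligner(scoring, gap_open, gap_extend, alphabet)
    score = aligner.score(seq_b, seq_a)
    if score <= max(min_score, 0.0):
        return []
    alignment = aligner.align(seq_b, seq_a)[0]
    matches, columns, query_res = _column_stats(alignment)
    key = (scoring, int(gap_open), int(gap_extend))
    lam, k = KARLIN_ALTSCHUL.get(key, KARLIN_ALTSCHUL[("blosum62", 11, 1)])
    evalue = k * len(seq_a) * len(seq_b) * math.exp(-lam * score)
    return [
        AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            identity_percent=100.0 * matches / columns if columns else 0.0,
            aln_len=max(columns, 1),
            query_cov_percent=100.0 * query_res / len(seq_a),
            score=float(score),
            evalue=evalue,
            query_start=int(alignment.aligned[1][0][0]) if len(alignment.aligned[1]) else 0,
            subject_start=int(alignment.aligned[0][0][0]) if len(alignment.aligned[0]) else 0,
        )
    ]


def local_score(seq_a: str, seq_b: str, scoring: str = "blosum62",
                gap_open: float = 11.0, gap_extend: float = 1.0,
                alphabet: str = "protein") -> float:
    """Score-only Smith-Waterman (cheaper than a full traceback)."""
    return float(_local_aligner(scoring, gap_open, gap_extend, alphabet).score(seq_b, seq_a))


def map_fragment_best_strand(
    fragment: str, fragment_rc: str, genome_seq: str
) -> tuple[float, float, int] | None:
    """Best-strand fragment placement: distance pass first, then one traceback.

    The forward strand is searched with an edit-distance cap of 0.55 times the
    fragment length (no optimal edit alignment of diverged or unrelated DNA
    exceeds that band in practice — random sequence aligns near 0.5), the
    reverse strand only has to beat the forward distance, and the cigar is
    computed once for the winner.  Same result as mapping both strands fully,
    at a fraction of the cost.
    """
    cap = int(0.55 * len(fragment)) + 1
    d_f = edlib.align(fragment, genome_seq, mode="HW", task="distance", k=cap)["editDistance"]
    cap_r = cap if d_f < 0 else min(cap, d_f)
    d_r = edlib.align(fragment_rc, genome_seq, mode="HW", task="distance", k=cap_r)["editDistance"]
    if d_f < 0 and d_r < 0:
        return None
    if d_r >= 0 and (d_f < 0 or d_r < d_f):
        winner, d = fragment_rc, d_r
    else:
        winner, d = fragment, d_f
    return map_fragment(winner, genome_seq, k=d)


def map_fragment(fragment: str, genome_seq: str, k: int = -1) -> tuple[float, float, int] | None:
    """Map a fragment into a genome by infix (free-end-gap) edit alignment.

    Fast backend for fragment-based ANI: returns (identity_percent,
    coverage_percent, aligned_columns) of the best placement, or None when
    edlib reports no alignment.  Identity is matches over alignment columns;
    the whole fragment is consumed, so coverage is measured as fragment
    residues in the alignment over fragment length (100 unless degenerate).
    """
    res = edlib.align(fragment, genome_seq, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    matches = columns = qres = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
            qres += n
        elif ch == "X":
            qres += n
        elif ch == "I":  # gap in target: consumes query
            qres += n
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * qres / len(fragment)
    return identity, coverage, columns


def k2p_from_counts(p: float, q: float) -> float:
    """Kimura two-parameter distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    P and Q are the proportions of aligned sites differing by a transition and
    a transversion.  Returns ``math.inf`` when the correction saturates
    (1-2P-Q <= 0 or 1-2Q <= 0), signalling an undefined distance.
    """
    if p < 0 or q < 0 or p + q > 1:
        raise ValueError("require P >= 0, Q >= 0, P + Q <= 1")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        return math.inf
    return -0.5 * math.log(a * math.sqrt(b))


def k2p_distance(aligned_a: str, aligned_b: str) -> float:
    """K2P distance from two equal-length aligned sequences.

    Columns containing gaps or ambiguous bases are dropped before computing
    the transition (P) and transversion (Q) proportions.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    sites = transitions = transversions = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _NT or y not in _NT:
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable (gap-free, unambiguous) columns")
    return k2p_from_counts(transitions / sites, transversions / sites)
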