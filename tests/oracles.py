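"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: plain full-matrix Gotoh
DP for alignment scores, exhaustive six-frame scanning for ORFs, and a
dendropy-based MRCA check for monophyly.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = -1e9


def sw_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman best local score, full-matrix affine-gap Gotoh DP.

    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(a), len(b)
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), NEG)  # gap in a (moving along b)
    f = np.full((n + 1, m + 1), NEG)  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - gap_open - gap_extend, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - gap_open - gap_extend, f[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return float(best)


def nw_score_free_ends(
    a: str, b: str, match: float = 1.0, mismatch: float = -2.0,
    gap_open: float = 5.0, gap_extend: float = 2.0,
) -> float:
    """Global score with free terminal gaps (semi-global Gotoh DP)."""
    n, m = len(a), len(b)
    h = np.full((n + 1, m + 1), NEG)
    e = np.full((n + 1, m + 1), NEG)
    f = np.full((n + 1, m + 1), NEG)
    h[0, :] = 0.0  # free leading gaps
    h[:, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - gap_open - gap_extend, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - gap_open - gap_extend, f[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h[i][j] = max(h[i - 1][j - 1] + s, e[i][j], f[i][j])
    # free trailing gaps: best over last row and column
    return float(max(h[n, :].max(), h[:, m].max()))


_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def orf_proteins(seq: str, min_len_nt: int) -> list[str]:
    """Exhaustive six-frame ORF scan; returns the translated proteins.

    Mirrors the contract (ATG to next in-frame stop, longest ORF per stop)
    via direct enumeration of every frame on both strands.
    """
    from Bio.Seq import Seq

    out = []
    for s in (seq, seq[::-1].translate(_COMP)):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            start = None
            for k, codon in enumerate(codons):
                if codon in _STOPS:
                    if start is not None:
                        orf = "".join(codons[start : k + 1])
                        if len(orf) >= min_len_nt:
                            out.append(str(Seq(orf).translate(table=11))[:-1])
                    start = None
                elif codon == "ATG" and start is None:
                    start = k
    return sorted(out)


def monophyletic_dendropy(newick: str, members: set[str]) -> bool:
    """Monophyly on an unrooted tree via dendropy MRCA, rooted at an outsider."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = {t.taxon.label for t in tree.leaf_node_iter()}
    outside = sorted(leaves - members)
    if not outside or len(members) == 1:
        return True
    out_node = [t for t in tree.leaf_node_iter() if t.taxon.label == outside[0]][0]
    tree.reroot_at_edge(out_node.edge, update_bipartitions=True)
    mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in members])
    under = {t.taxon.label for t in mrca.leaf_iter()}
    return under == members


def random_unrooted_tree(labels: list[str], rng: np.random.Generator) -> str:
    """Random unrooted binary topology with random branch lengths, as newick."""
    nodes = [f"{x}:{rng.uniform(0.1, 2.0):.6f}" for x in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return f"({','.join(nodes)});"
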