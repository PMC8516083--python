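"""Distance trees, monophyly testing, MLSA markers and consensus reassignment.

Neighbor-joining (Saitou-Nei) is the built-in tree method; externally built
phylogenomic trees are consumed as newick.  Monophyly is decided on the
unrooted tree via edge bipartitions, so verdicts do not depend on rooting.
The consensus engine fuses similarity clusters with tree monophyly into
per-genome keep / novel-genus / transfer proposals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .align import align_local
from .genomes import ProteomeRecord

MARKER_ORDER = ("fusA", "gyrB", "recA", "rpoB")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(distances: np.ndarray, labels: list[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Classic Saitou-Nei agglomeration under the Q-criterion.  Ties are broken
    toward the lexicographically smallest label pair so output is
    deterministic; negative branch-length estimates are clamped to 0 (the
    clamped nodes carry ``negative_branch=True``).  Returns an unrooted tree
    (trifurcating root) as an skbio TreeNode.
    """
    d = np.asarray(distances, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric (tolerance 1e-9)")
    if not np.isfinite(d).all():
        raise ValueError("distance matrix contains non-finite entries (saturation?)")

    nodes: list[TreeNode] = [TreeNode(name=x) for x in labels]
    names: list[str] = list(labels)  # smallest leaf name under each active node
    active = list(range(n))
    dm = d.copy()

    def _clamp(length: float, node: TreeNode) -> float:
        if length < 0:
            node.negative_branch = True
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        pick = min(
            (tuple(sorted((names[active[i]], names[active[j]]))), (i, j))
            for i, j in ties
            if i < j
        )[1]
        i, j = pick
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = _clamp(li, child_i)
        child_j.length = _clamp(lj, child_j)
        parent = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (dm[ai, :] + dm[aj, :] - dij)
        nodes.append(parent)
        names.append(min(names[ai], names[aj]))
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = new_d
        dm[:-1, -1] = new_d
        dm[-1, -1] = 0.0
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # final three-way join: branch lengths from the three-point formulas
    a, b, c = active
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = _clamp(length, node)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def read_newick(source) -> TreeNode:
    """Read a newick tree (path or string); rejects duplicate leaf labels."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read(io.StringIO(source), convert_underscores=False)
    else:
        tree = TreeNode.read(str(source), convert_underscores=False)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels in newick input")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------


@dataclass
class MonophylyVerdict:
    genus: str
    monophyletic: bool
    blocking_leaves: list[str] = field(default_factory=list)


def _bipartitions(tree: TreeNode) -> list[frozenset]:
    """Leaf sets on one side of every edge (terminal included) of the tree."""
    out = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            out.append(frozenset([node.name]))
        else:
            out.append(frozenset(t.name for t in node.tips()))
    return out


def check_monophyly(tree: TreeNode, labeling: dict[str, str]) -> dict[str, MonophylyVerdict]:
    """Per-genus monophyly on the unrooted tree via edge bipartitions.

    A genus is monophyletic iff some edge separates exactly its leaves from
    the rest (either side of the bipartition may match); singletons are
    trivially monophyletic.  For failing genera, ``blocking_leaves`` is the
    smallest set of foreign leaves inside the genus's tightest enclosing
    clade — the intruders a curator would inspect first.
    """
    leaves = {t.name for t in tree.tips()}
    unlabeled = leaves - labeling.keys()
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {sorted(unlabeled)}")
    genera: dict[str, set] = {}
    for leaf in leaves:
        genera.setdefault(labeling[leaf], set()).add(leaf)
    parts = _bipartitions(tree)
    verdicts = {}
    for genus, members in sorted(genera.items()):
        members_f = frozenset(members)
        complement = frozenset(leaves - members)
        if len(members) == 1 or members_f in parts or complement in parts or not complement:
            verdicts[genus] = MonophylyVerdict(genus, True)
            continue
        # tightest side containing all members, on either orientation
        enclosing = min(
            (side for side in (parts + [frozenset(leaves)])
             for side in (side, frozenset(leaves - side))
             if members_f <= side),
            key=len,
        )
        verdicts[genus] = MonophylyVerdict(genus, False, sorted(enclosing - members_f))
    return verdicts


# ---------------------------------------------------------------------------
# MLSA markers
# ---------------------------------------------------------------------------


@dataclass
class MarkerSet:
    """Per-genome housekeeping-marker proteins in fixed concatenation order."""

    genome_id: str
    markers: dict[str, str]  # marker name -> protein sequence
    missing: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing


def extract_markers(
    proteome: ProteomeRecord,
    queries: dict[str, str],
    min_identity: float = 30.0,
    min_cov: float = 50.0,
) -> MarkerSet:
    """Pull housekeeping markers out of a proteome by best local alignment.

    For each query marker the best-scoring hit above the identity/coverage
    filters is taken (ties: higher score, then lexicographic protein id);
    markers with no qualifying hit are flagged missing, never fabricated.
    """
    if not queries:
        raise ValueError("empty marker query set")
    markers: dict[str, str] = {}
    missing: list[str] = []
    for marker in sorted(queries, key=lambda mk: (MARKER_ORDER.index(mk) if mk in MARKER_ORDER else 99, mk)):
        qseq = queries[marker]
        best = None
        best_key = None
        for pid in sorted(proteome.proteins):
            hits = align_local(qseq, proteome.proteins[pid], query_id=marker, subject_id=pid)
            if not hits:
                continue
            hit = hits[0]
            cov = 100.0 * hit.aln_len / len(qseq)
            if hit.identity_percent < min_identity or cov < min_cov:
                continue
            key = (-hit.score, pid)
            if best_key is None or key < best_key:
                best_key, best = key, pid
        if best is None:
            missing.append(marker)
        else:
            markers[marker] = proteome.proteins[best]
    return MarkerSet(genome_id=proteome.genome_id, markers=markers, missing=missing)


def concatenate_markers(
    aligned_blocks: dict[str, dict[str, str]],
    order: tuple[str, ...] = MARKER_ORDER,
) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    """Concatenate per-marker aligned blocks into an MLSA supermatrix.

    ``aligned_blocks`` maps marker name -> {genome_id: aligned sequence}; all
    sequences within a marker must share one length.  Genomes missing any
    marker are excluded with a warning.  Returns (supermatrix rows, 1-based
    inclusive column range per marker, in concatenation order).
    """
    order = tuple(m for m in order if m in aligned_blocks) + tuple(
        m for m in sorted(aligned_blocks) if m not in order
    )
    widths = {}
    for marker in order:
        lens = {len(s) for s in aligned_blocks[marker].values()}
        if len(lens) != 1:
            raise ValueError(f"marker {marker!r}: unequal aligned lengths {sorted(lens)}")
        widths[marker] = lens.pop()
    genomes = set.union(*(set(b) for b in aligned_blocks.values()))
    complete = sorted(g for g in genomes if all(g in aligned_blocks[m] for m in order))
    dropped = sorted(genomes - set(complete))
    if dropped:
        import warnings

        warnings.warn(f"genomes missing markers excluded from concatenation: {dropped}")
    ranges: dict[str, tuple[int, int]] = {}
    start = 1
    for marker in order:
        ranges[marker] = (start, start + widths[marker] - 1)
        start += widths[marker]
    rows = {g: "".join(aligned_blocks[m][g] for m in order) for g in complete}
    return rows, ranges


# ---------------------------------------------------------------------------
# consensus reassignment
# ---------------------------------------------------------------------------


@dataclass
class ReassignmentProposal:
    genome_id: str
    original_genus: str
    proposal: str  # "keep" | "novel_genus" | "transfer:<family>" | "conflict"
    evidence: list[str] = field(default_factory=list)


def _family_transfer_targets(
    tree: TreeNode, genus_members: dict[str, set], families: dict[str, str]
) -> dict[str, str]:
    """Genera whose relabeling to another family restores family monophyly.

    For each genus labelled family F, test every other family F': if moving
    the genus to F' makes both the donor and recipient family leaf sets
    compatible with some tree bipartition, the genus is proposed for transfer
    to F'.  Mirrors how a genus nested inside the other family's branch is
    read off a phylogenomic tree.
    """
    leaves = {t.name for t in tree.tips()}
    parts = set(_bipartitions(tree))
    parts |= {frozenset(leaves - p) for p in parts}

    def mono(group: frozenset) -> bool:
        return len(group) <= 1 or group in parts or group == leaves

    fam_members: dict[str, set] = {}
    for genus, members in genus_members.items():
        fam_members.setdefault(families[genus], set()).update(members)
    candidates: dict[str, str] = {}
    for genus, members in sorted(genus_members.items()):
        f_own = families[genus]
        if mono(frozenset(fam_members[f_own])):
            continue
        for f_new in sorted(set(families.values()) - {f_own}):
            donor = frozenset(fam_members[f_own] - members)
            recipient = frozenset(fam_members[f_new] | members)
            others_ok = all(
                mono(frozenset(fam_members[f]))
                for f in fam_members
                if f not in (f_own, f_new)
            )
            if mono(donor) and mono(recipient) and others_ok:
                candidates[genus] = f_new
                break
    if not candidates:
        return {}
    # several moves can restore monophyly on an unrooted tree; the nested
    # genus is read off as the unique smallest one (fewest leaves moved)
    smallest = min(len(genus_members[g]) for g in candidates)
    minimal = [g for g in candidates if len(genus_members[g]) == smallest]
    if len(minimal) != 1:
        return {}
    return {minimal[0]: candidates[minimal[0]]}


def consensus_reassignment(
    clusters: dict[str, int],
    tree: TreeNode,
    genus_labels: dict[str, str],
    family_labels: dict[str, str] | None = None,
    index_evidence: dict[str, list[str]] | None = None,
) -> list[ReassignmentProposal]:
    """Fuse similarity clusters and tree monophyly into taxonomy proposals.

    A genome keeps its genus iff its cluster contains exactly its (remaining)
    genus mates and the genus is monophyletic on the tree.  A genome that is
    both a singleton cluster and its own branch while its genus has other
    members is proposed as a novel genus.  A monophyletic, single-cluster
    genus sitting inside another family's branch is proposed for transfer to
    that family (genus retained).  Anything else is surfaced as a conflict,
    never silently resolved.
    """
    leaves = {t.name for t in tree.tips()}
    if set(clusters) != leaves:
        raise ValueError("cluster labels and tree leaves must cover the same genomes")
    missing = leaves - genus_labels.keys()
    if missing:
        raise ValueError(f"genomes without genus labels: {sorted(missing)}")
    index_evidence = index_evidence or {}
    genus_members: dict[str, set] = {}
    for g in leaves:
        genus_members.setdefault(genus_labels[g], set()).add(g)
    cluster_members: dict[int, set] = {}
    for g, c in clusters.items():
        cluster_members.setdefault(c, set()).add(g)
    verdicts = check_monophyly(tree, genus_labels)

    # genomes that leave their genus: singleton cluster + own branch
    novel: set = set()
    for g in sorted(leaves):
        genus = genus_labels[g]
        if len(genus_members[genus]) > 1 and cluster_members[clusters[g]] == {g}:
            novel.add(g)

    # family-level placement of the remaining genera
    families = dict(family_labels or {g: "unplaced" for g in genus_members})
    remaining_labels = {
        g: (f"novel:{g}" if g in novel else genus_labels[g]) for g in leaves
    }
    remaining_members: dict[str, set] = {}
    for g in leaves:
        remaining_members.setdefault(remaining_labels[g], set()).add(g)
    fam_of = {
        genus: families.get(genus.split(":", 1)[-1] if genus.startswith("novel:") else genus,
                            families.get(genus_labels.get(genus.split(":", 1)[-1], ""), "unplaced"))
        for genus in remaining_members
    }
    # novel singleton genera inherit their original genus's family for the test
    for genus in remaining_members:
        if genus.startswith("novel:"):
            fam_of[genus] = families.get(genus_labels[genus.split(":", 1)[1]], "unplaced")
    transfers = (
        _family_transfer_targets(tree, remaining_members, fam_of) if family_labels else {}
    )
    remaining_verdicts = check_monophyly(tree, remaining_labels)

    proposals = []
    for g in sorted(leaves):
        genus = genus_labels[g]
        ev = list(index_evidence.get(g, []))
        if g in novel:
            proposals.append(
                ReassignmentProposal(
                    g, genus, "novel_genus",
                    ev + [f"singleton cluster and own branch, apart from {genus}"],
                )
            )
            continue
        label = remaining_labels[g]
        mates = remaining_members[label]
        same_cluster = cluster_members[clusters[g]] == mates
        mono = remaining_verdicts[label].monophyletic
        if same_cluster and mono:
            if label in transfers:
                proposals.append(
                    ReassignmentProposal(
                        g, genus, f"transfer:{transfers[label]}",
                        ev + [f"genus {genus} monophyletic but nested in family "
                              f"{transfers[label]}"],
                    )
                )
            else:
                proposals.append(ReassignmentProposal(g, genus, "keep", ev))
        else:
            reasons = []
            if not same_cluster:
                others = sorted({genus_labels[x] for x in cluster_members[clusters[g]]} - {genus})
                reasons.append(
                    f"cluster does not coincide with genus mates"
                    + (f" (cluster spans {', '.join([genus] + others)})" if others else "")
                )
            if not mono:
                reasons.append(
                    f"genus non-monophyletic (blocking leaves: "
                    f"{remaining_verdicts[label].blocking_leaves})"
                )
            proposals.append(ReassignmentProposal(g, genus, "conflict", ev + reasons))
    return proposals
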