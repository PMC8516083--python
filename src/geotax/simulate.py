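"""Synthetic genome evolution with a planted genus/species hierarchy.

The generator builds an ancestral bacterial genome (protein-coding genes laid
end-to-end with intergenic filler at a target G+C), evolves it down a
two-level tree — fast inter-genus branches, slow intra-genus branches — with
i.i.d. nucleotide substitutions at transition:transversion 2:1 (so the K2P
correction applies exactly), samples gene loss on inter-genus branches (lost
genes are replaced by neutral filler, driving POCP down), and evolves a 16S
gene tenfold slower than the genome (a slow marker that under-resolves
genera, as real SSU data does).  Everything is driven by one seeded
generator: identical seeds give byte-identical FASTA output.

Substitutions are i.i.d. per site without rate heterogeneity, which keeps the
closed-form expectations for ANI, POCP and K2P testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomes import GenomeRecord, ProteomeRecord, write_fasta
from .phylo import read_newick

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}
# transition partner of A,C,G,T (A<->G, C<->T)
_TS = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion partners per base
_TV = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for one simulated collection.

    Rates are substitution probabilities per site per branch: ``p_s`` on
    intra-genus (species) branches, ``p_g`` on inter-genus branches, with
    ``p_s < p_g`` so genus structure dominates.  ``gene_loss_prob`` applies
    per gene per inter-genus branch.
    """

    n_genera: int = 3
    species_per_genus: int = 3
    genome_len_bp: int = 200_000
    n_genes: int = 200
    gene_len_aa: int = 220
    gc_target: float = 62.0
    p_s: float = 0.02
    p_g: float = 0.12
    gene_loss_prob: float = 0.15
    ssu_len: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_s < self.p_g < 0.75):
            raise ValueError("require 0 <= p_s < p_g < 0.75")
        if not (0.0 <= self.gene_loss_prob < 1.0):
            raise ValueError("gene_loss_prob must lie in [0, 1)")
        if min(self.n_genera, self.species_per_genus, self.genome_len_bp,
               self.n_genes, self.gene_len_aa, self.ssu_len) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_genes * (self.gene_len_aa + 2) * 3 > self.genome_len_bp:
            raise ValueError("genes do not fit in genome_len_bp")


@dataclass
class Ancestor:
    """The root genome: gene coordinates over one contig, plus its 16S gene."""

    sequence: np.ndarray  # uint8 base codes 0..3
    gene_spans: list[tuple[int, int]]  # 0-based half-open, in-frame
    ssu: np.ndarray


@dataclass
class SimulatedCollection:
    config: SimConfig
    tree_newick: str
    labels: dict[str, str]  # tip -> genus
    genomes: dict[str, GenomeRecord] = field(default_factory=dict)
    proteomes: dict[str, ProteomeRecord] = field(default_factory=dict)
    ssu: dict[str, str] = field(default_factory=dict)
    gene_presence: dict[str, np.ndarray] = field(default_factory=dict)
    ancestor: "Ancestor | None" = None

    @property
    def tree(self):
        return read_newick(self.tree_newick)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=probs).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _remove_stops(codes: np.ndarray, rng: np.random.Generator, frame_start: int, frame_end: int) -> None:
    """Resample in-frame stop codons in place (codes sliced in frame)."""
    seq = codes[frame_start:frame_end]
    for i in range(0, len(seq) - 2, 3):
        while _decode(seq[i : i + 3]) in _STOPS:
            seq[i + rng.integers(3)] = rng.integers(4)


def _make_ancestor(config: SimConfig, rng: np.random.Generator) -> Ancestor:
    gene_nt = (config.gene_len_aa + 2) * 3  # start + body + stop
    coding = config.n_genes * gene_nt
    filler_total = config.genome_len_bp - coding
    gap = filler_total // (config.n_genes + 1)
    seq = _random_bases(rng, config.genome_len_bp, config.gc_target)
    spans = []
    pos = gap
    atg = np.array([_CODE[c] for c in "ATG"], dtype=np.uint8)
    stop = np.array([_CODE[c] for c in "TAA"], dtype=np.uint8)
    for _ in range(config.n_genes):
        seq[pos : pos + 3] = atg
        _remove_stops(seq, rng, pos + 3, pos + gene_nt - 3)
        seq[pos + gene_nt - 3 : pos + gene_nt] = stop
        spans.append((pos, pos + gene_nt))
        pos += gene_nt + gap
    ssu = _random_bases(rng, config.ssu_len, config.gc_target)
    return Ancestor(sequence=seq, gene_spans=spans, ssu=ssu)


def mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitutions at probability p per site, ts:tv 2:1."""
    out = codes.copy()
    if p <= 0:
        return out
    hits = np.nonzero(rng.random(len(codes)) < p)[0]
    if len(hits) == 0:
        return out
    kinds = rng.random(len(hits))
    ts = hits[kinds < 2.0 / 3.0]
    tv = hits[kinds >= 2.0 / 3.0]
    out[ts] = _TS[out[ts]]
    which = rng.integers(2, size=len(tv))
    out[tv] = _TV[out[tv], which]
    return out


def simulate_taxonomy(config: SimConfig):
    """Build the planted hierarchy: true tree, labels and ancestor genome.

    The tree is a star of genera at the root, each genus a star of species
    tips: inter-genus branches carry rate ``p_g``, intra-genus branches
    ``p_s``.  Branch lengths in the emitted newick are the branch
    substitution probabilities.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _make_ancestor(config, rng)
    genera = [f"Genus{chr(ord('A') + i)}" for i in range(config.n_genera)]
    labels = {}
    parts = []
    for gi, genus in enumerate(genera):
        tips = []
        for si in range(config.species_per_genus):
            tip = f"{genus}_sp{si + 1}"
            labels[tip] = genus
            tips.append(f"{tip}:{config.p_s}")
        if config.n_genera == 1:
            # a single genus has no inter-genus branch: the root is the genus
            parts.extend(tips)
        elif len(tips) == 1:
            parts.append(f"{tips[0].split(':')[0]}:{config.p_g}")
        else:
            parts.append(f"({','.join(tips)}){genus}:{config.p_g}")
    newick = f"({','.join(parts)})root;"
    return newick, labels, ancestor, rng


def evolve_collection(
    ancestor: Ancestor, newick: str, config: SimConfig, rng: np.random.Generator
) -> SimulatedCollection:
    """Evolve the ancestor down the tree into per-tip genome/proteome/16S.

    Lost genes (sampled per inter-genus branch) are cut from the proteome and
    replaced in the genome by neutral filler of the same length; proteomes
    are re-derived by translating the surviving genes of each tip's genome.
    """
    from Bio.Seq import Seq

    collection = SimulatedCollection(config=config, tree_newick=newick, labels={})
    tree = read_newick(newick)
    n_genes = len(ancestor.gene_spans)

    def recurse(node, genome: np.ndarray, ssu: np.ndarray, presence: np.ndarray, inter: bool):
        for child in sorted(node.children, key=lambda c: str(c.name)):
            p = float(child.length or 0.0)
            g = mutate(genome, p, rng)
            s = mutate(ssu, p / 10.0, rng)
            pres = presence.copy()
            if inter and config.gene_loss_prob > 0:
                lost = rng.random(n_genes) < config.gene_loss_prob
                for k in np.nonzero(lost & pres)[0]:
                    a, b = ancestor.gene_spans[k]
                    g[a:b] = _random_bases(rng, b - a, config.gc_target)
                pres &= ~lost
            if child.is_tip():
                tip = str(child.name)
                seq = _decode(g)
                collection.genomes[tip] = GenomeRecord(tip, [seq], source="simulated")
                proteins = {}
                for k in np.nonzero(pres)[0]:
                    a, b = ancestor.gene_spans[k]
                    aa = str(Seq(seq[a:b]).translate(table=11))
                    proteins[f"{tip}_g{k:04d}"] = aa[:-1].replace("*", "X") if aa.endswith("*") else aa.replace("*", "X")
                collection.proteomes[tip] = ProteomeRecord(tip, proteins, source="simulated")
                collection.ssu[tip] = _decode(s)
                collection.gene_presence[tip] = pres
            else:
                recurse(child, g, s, pres, inter=False)

    # children of the root are genus ancestors (inter-genus branches), except
    # in the degenerate single-genus case where the root is the genus itself
    recurse(tree, ancestor.sequence, ancestor.ssu, np.ones(n_genes, dtype=bool),
            inter=config.n_genera > 1)
    return collection


def simulate_collection(config: SimConfig) -> SimulatedCollection:
    """One-call interface: planted taxonomy plus the evolved collection."""
    newick, labels, ancestor, rng = simulate_taxonomy(config)
    collection = evolve_collection(ancestor, newick, config, rng)
    collection.labels.update(labels)
    collection.ancestor = ancestor
    return collection


def spawn_descendant(
    collection: SimulatedCollection,
    tip: str,
    p: float,
    name: str,
    rng: np.random.Generator,
) -> SimulatedCollection:
    """Evolve one extra tip from an existing one at substitution rate ``p``.

    No gene loss is applied, so the descendant is a conspecific strain (small
    ``p``) or congeneric relative (larger ``p``) of ``tip``; the new tip is
    appended to the collection (same genus label as its parent) and returned
    with it.
    """
    from Bio.Seq import Seq

    if collection.ancestor is None:
        raise ValueError("collection lacks ancestor coordinates")
    codes = np.frombuffer(collection.genomes[tip].contigs[0].encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
    g = mutate(lut[codes], p, rng)
    s = mutate(lut[np.frombuffer(collection.ssu[tip].encode(), dtype=np.uint8)], p / 10.0, rng)
    seq = _decode(g)
    pres = collection.gene_presence[tip]
    proteins = {}
    for k in np.nonzero(pres)[0]:
        a, b = collection.ancestor.gene_spans[k]
        aa = str(Seq(seq[a:b]).translate(table=11))
        proteins[f"{name}_g{k:04d}"] = (aa[:-1] if aa.endswith("*") else aa).replace("*", "X")
    collection.genomes[name] = GenomeRecord(name, [seq], source="simulated")
    collection.proteomes[name] = ProteomeRecord(name, proteins, source="simulated")
    collection.ssu[name] = _decode(s)
    collection.gene_presence[name] = pres.copy()
    collection.labels[name] = collection.labels[tip]
    return collection


def write_collection(collection: SimulatedCollection, outdir: str | Path) -> Path:
    """Emit genomes/*.fna, proteomes/*.faa, ssu/*.fna and truth files."""
    outdir = Path(outdir)
    for sub in ("genomes", "proteomes", "ssu", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for tip in sorted(collection.genomes):
        write_fasta(collection.genomes[tip], outdir / "genomes" / f"{tip}.fna")
        write_fasta(collection.proteomes[tip], outdir / "proteomes" / f"{tip}.faa")
        write_fasta([(f"{tip}_16S", collection.ssu[tip])], outdir / "ssu" / f"{tip}.fna")
    with open(outdir / "truth" / "labels.tsv", "w") as fh:
        fh.write("genome_id\tgenus\n")
        for tip in sorted(collection.labels):
            fh.write(f"{tip}\t{collection.labels[tip]}\n")
    (outdir / "truth" / "tree.nwk").write_text(collection.tree_newick + "\n")
    return outdir
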