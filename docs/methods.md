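# Methods

## The problem

Prokaryotic genera and species are increasingly delimited from whole-genome
evidence rather than 16S rRNA identity alone. For groups such as the
*Geobacterales* — iron-reducing soil and sediment bacteria whose generic
boundaries have been redrawn repeatedly — the practical workflow is: compute
pairwise genome similarity indices over all type-strain genomes, find the
"parting line" that separates intra-genus from inter-genus pairs, cut an
average-linkage dendrogram at that line, confront the resulting clusters with
a phylogenomic tree, and propose reassignments only where similarity clusters
and tree monophyly agree. `geotax` implements that workflow as a tested
library with a synthetic-evolution test bed, so every stage can be validated
against planted ground truth without downloading genome assemblies.

## Similarity indices

Four indices, each a percentage with a per-pair unit count:

* **ANIb** (average nucleotide identity, fragment variant). The query genome
  is chopped into consecutive 1,020 bp fragments (a trailing piece is kept if
  ≥ 100 bp). Each fragment is placed in the subject genome on both strands by
  infix alignment; fragments are retained when the best placement has
  ≥ 30 % identity over ≥ 70 % of the fragment. The directional ANI is the
  mean identity of retained fragments and the reported value is the mean of
  the two directions. Fragment placement runs on a bit-vector edit-distance
  aligner (edlib) with a distance cap of 0.55 × fragment length per strand;
  since optimal edit alignment of unrelated DNA lands near 0.5, the cap
  discards nothing that a practitioner would call a hit while bounding the
  worst-case cost. Note the dialect difference from word-seeded local
  search tools: unit-cost edit alignment assigns ~50 % identity to unrelated
  sequence instead of producing no hit, so the 30 % identity floor is
  effectively never the active filter.
* **AAI** (average amino-acid identity). Best hits are computed in both
  directions between proteomes; a reciprocal best-hit pair is kept when each
  protein is the other's best hit and the alignment has ≥ 30 % identity with
  ≥ 70 % coverage of the shorter sequence. AAI is the mean of the two
  directional identities over kept pairs.
* **POCP** (percentage of conserved proteins), 100·(C1+C2)/(T1+T2): C counts
  proteins with a hit in the other proteome at E < 10⁻⁵, identity > 40 % and
  aligned region > 50 % of the query length; T are total protein counts.
* **SSU identity**: global nucleotide alignment of 16S rRNA genes with affine
  gaps and free terminal gaps; identity over aligned columns excluding
  terminal gaps. Sequences below 1,200 nt trigger a warning but are accepted.

Protein searches use exact Smith–Waterman (BLOSUM62, gap open 11, extend 1)
on a shortlist of candidates ranked by shared 4-mer count (top 8 per query).
The shortlist plays the role word seeding plays in production search tools;
the alignment itself is exact DP, and the test suite checks the scores
against an independent full-matrix Gotoh implementation. E-values follow
Karlin–Altschul statistics with the published gapped parameters
(λ = 0.267, K = 0.041 for BLOSUM62/11,1; λ = 1.28, K = 0.46 for +1/−2
nucleotide scoring) and the search space scaled to the target proteome size.

An index with no passing units is reported as *undefined*, never 0, so a
degenerate input cannot imitate maximal divergence.

## Distances and trees

The Kimura two-parameter distance d = −½ ln[(1 − 2P − Q)√(1 − 2Q)] is
computed from transition (P) and transversion (Q) proportions after dropping
gapped and ambiguous columns; saturation (non-positive log argument) is
signalled as an infinite distance. Neighbor joining follows Saitou–Nei with
the standard Q-criterion; ties are broken toward the lexicographically
smallest label pair so trees are bit-reproducible, and negative branch-length
estimates are clamped to zero with a flag. On additive matrices NJ provably
recovers the generating topology and path lengths; the suite asserts this to
machine precision.

Monophyly is decided on the unrooted tree: a genus is monophyletic iff some
edge bipartition (terminal edges included) separates exactly its leaves.
Verdicts are therefore invariant under re-rooting. For failing genera the
foreign leaves inside the tightest enclosing clade are reported.

## Thresholds, clustering, classification

* **Parting line**: off-diagonal pair values are split into intra-/inter-genus
  by the label table. If separable, the threshold is the midpoint of the gap
  and has zero violations; otherwise an exhaustive scan (including the
  all-inter sentinel above the maximum) picks the threshold minimising
  misclassified pairs, ties resolved toward the lower value.
* **Clustering**: average linkage (UPGMA) on dissimilarity 100 − similarity,
  cut at 100 − threshold. Average linkage matches the dendrogram style used
  in genus-demarcation work; clusters are renumbered by first appearance so
  output is deterministic.
* **Classification** uses the published cut-offs: genus thresholds AAI 70,
  POCP 65, ANI 74 (AAI primary, the others corroborating; discordant verdicts
  surface as `conflict`, never silently resolved), species thresholds ANI 95
  and AAI 95 to the same reference (95 is the conservative low end of the
  95–96 range, biased toward calling novelty), and 16S advisory marks at
  94.5 (genus) and 98.65 (species) that are reported but never decisive.

## Consensus reassignment

A genome keeps its genus iff its similarity cluster contains exactly its
remaining genus mates *and* the genus is monophyletic. A genome in a
singleton cluster while its genus has other members is proposed as a novel
genus. After removing such strains, a genus that is monophyletic and a single
cluster but breaks its family's monophyly is tested for transfer: relabelling
it to another family must restore a bipartition-compatible family partition.
On an unrooted tree several single-genus moves can restore compatibility, so
the transfer is proposed only when the move is the unique smallest one
(fewest leaves moved) — the way a curator reads "the small genus nested in
the other family's branch". Everything else is surfaced as `conflict`.

## The synthetic generator

`SimConfig` defaults are the study conditions used throughout the tests and
the acceptance script: 3 genera × 3 species, 200 kb genomes, 200 genes of
220 aa, G+C target 62 % (typical of the taxa this workflow was built around),
intra-genus branch substitution probability p_s = 0.02, inter-genus
p_g = 0.12, gene-loss probability 0.15 per inter-genus branch, 1,500 nt SSU.
These sizes keep a full all-vs-all analysis on one CPU in minutes while
leaving every statistic (fragment counts, RBH counts, binomial gene-retention
spread) in a regime where closed-form expectations are sharp.

The ancestor lays genes end-to-end with intergenic filler drawn at the G+C
target; substitutions are i.i.d. per site per branch with a 2:1
transition:transversion ratio (so the K2P correction applies exactly); gene
loss removes the protein and replaces the locus with neutral filler; the SSU
evolves at one tenth of the branch rate, reproducing the classic observation
that 16S under-resolves genera. All draws flow from one seeded generator:
identical seeds give byte-identical FASTA.

What the generator does *not* emulate — rate heterogeneity across sites,
codon usage, rearrangements, horizontal transfer, pseudogenes, assembly
fragmentation or contamination — bounds what passing tests show: they verify
the statistical machinery and its calibration on an idealised substitution
process, not robustness to real-genome artefacts. Two consequences worth
knowing: evolved tips drift below the ancestral G+C target (the substitution
process is G+C-blind, so only the synthesized ancestor is guaranteed within
0.5 points of the target), and closed-form index expectations
(ANI ≈ 100·(1 − (1 − (1 − p)²)), POCP ≈ 100·(1 − q)) ignore convergent
substitutions, which is why tolerances are stated as absolute margins or
delta-method standard errors rather than exact equalities.

## Numerical choices

* Alignment traceback ties follow the backend's fixed enumeration order;
  scores (which the indices consume) are tie-free.
* Matrices are symmetrised by construction (each unordered pair computed
  once); asymmetric input beyond 1e-9 is rejected.
* Percentages are written with one decimal in TSV output; JSON keeps full
  precision.
* Degenerate inputs fail loudly: empty FASTA, duplicate ids, all-ambiguous
  genomes, non-symmetric distance matrices, saturated distances inside NJ.

## Known limitations

* The internal ORF caller (six-frame, ATG-to-stop, table 11) is a stand-in so
  synthetic genomes are self-contained; real analyses should supply
  annotator-produced proteomes.
* Edit-distance fragment identity differs from scored local alignment for
  highly diverged pairs (see ANIb note above); within the intended regime
  (homologous genomes above ~60 % identity) the two agree closely.
* The k-mer shortlist can in principle miss a true best hit below ~30 %
  identity; such pairs are far below every decision threshold used here.
* Threshold inference formalises the parting line as midpoint /
  minimum-violation; where the intra/inter distributions overlap heavily the
  reported violation count, not the threshold itself, carries the signal.
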