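"""Matrix assembly, clustering, threshold inference and genome classification.

The demarcation logic formalises how taxonomists read a block of pairwise
similarity values: build the labelled matrix, cut an average-linkage
dendrogram at a similarity threshold, and infer genus thresholds as the
"parting line" between intra- and inter-genus pair distributions.  AAI is the
primary genus criterion (70%), corroborated by POCP (65%) and ANI (74%);
species are called at ANI >= 95 and AAI >= 95; 16S verdicts are advisory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

GENUS_THRESHOLDS = {"AAI": 70.0, "POCP": 65.0, "ANI": 74.0}
SPECIES_THRESHOLDS = {"ANI": 95.0, "AAI": 95.0}
SSU_ADVISORY = {"species": 98.65, "genus": 94.5}


@dataclass
class SimilarityMatrix:
    """Labelled symmetric matrix of one similarity index (percent).

    Missing (undefined) entries are NaN; the diagonal is 100 by construction.
    """

    labels: list[str]
    values: np.ndarray
    index_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-9
        ):
            raise ValueError("matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path, index_kind: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), index_kind)

    def to_phylip(self, path) -> None:
        """Write the square matrix in PHYLIP format (taxon count header)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = "\t".join(f"{v:.6f}" for v in row)
                fh.write(f"{label}\t{cells}\n")

    @classmethod
    def from_phylip(cls, path, index_kind: str) -> "SimilarityMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(labels) != n:
            raise ValueError(f"PHYLIP header declares {n} taxa, found {len(labels)}")
        return cls(labels, np.array(rows), index_kind)

    def pair_values(self) -> list[tuple[str, str, float]]:
        """Lower-triangle (a, b, value) pairs, self-pairs excluded."""
        out = []
        for i in range(len(self.labels)):
            for j in range(i):
                out.append((self.labels[i], self.labels[j], float(self.values[i, j])))
        return out


@dataclass
class ThresholdReport:
    """A 'parting line' between intra- and inter-genus pair values."""

    index_kind: str
    intra_values: list[tuple[str, str, float]]
    inter_values: list[tuple[str, str, float]]
    min_intra: float
    max_inter: float
    threshold: float
    n_violations: int

    @property
    def separable(self) -> bool:
        return self.max_inter < self.min_intra


@dataclass
class TaxonomyAssignment:
    """Machine-readable rank proposal for one genome with its evidence."""

    genome_id: str
    nearest_reference: str | None
    best_values: dict[str, float]
    genus_call: str  # "assigned:<genus>" | "novel_genus" | "conflict"
    species_call: str  # "assigned:<species>" | "novel_species" | "n/a"
    evidence: list[str] = field(default_factory=list)


def build_matrix(members: dict, index_kind: str, pair_fn, **params) -> SimilarityMatrix:
    """All-vs-all index matrix over a collection.

    ``members`` maps genome_id to whatever record ``pair_fn`` consumes
    (GenomeRecord, ProteomeRecord or a 16S string); ``pair_fn(a, b, **params)``
    must return an IndexValue.  Each unordered pair is computed once, the
    matrix is symmetrised, the diagonal set to 100 and undefined values kept
    as NaN.
    """
    labels = sorted(members)
    if len(labels) < 2:
        raise ValueError("need at least two collection members")
    n = len(labels)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i):
            iv = pair_fn(members[labels[i]], members[labels[j]], **params)
            values[i, j] = values[j, i] = np.nan if iv.value_percent is None else iv.value_percent
    return SimilarityMatrix(labels, values, index_kind)


def cluster_and_cut(matrix: SimilarityMatrix, threshold: float):
    """Average-linkage clusters at a similarity threshold, plus the dendrogram.

    Agglomerates on dissimilarity 100 - similarity and cuts at 100 -
    ``threshold``; returns ({genome_id: cluster_index}, scipy linkage matrix).
    Cluster indices are renumbered by first appearance in label order so
    output is deterministic.
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must lie in (0, 100)")
    values, labels = matrix.values, matrix.labels
    if not matrix.complete:
        keep = [i for i in range(len(labels)) if not np.isnan(values[i]).any()]
        if len(keep) < 2:
            raise ValueError("fewer than two genomes with complete rows")
        import warnings

        warnings.warn(
            f"matrix has missing values; clustering the complete {len(keep)}-genome submatrix"
        )
        labels = [labels[i] for i in keep]
        values = values[np.ix_(keep, keep)]
    dissim = 100.0 - values
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    link = linkage(condensed, method="average")
    flat = fcluster(link, t=100.0 - threshold, criterion="distance")
    remap: dict[int, int] = {}
    clusters = {}
    for label, c in zip(labels, flat):
        remap.setdefault(int(c), len(remap) + 1)
        clusters[label] = remap[int(c)]
    return clusters, link


def infer_threshold(matrix: SimilarityMatrix, labeling: dict[str, str]) -> ThresholdReport:
    """Infer a rank-demarcation threshold from labelled pairs.

    Off-diagonal pair values are split into intra- and inter-genus by
    ``labeling``.  When the two distributions are separable the threshold is
    the midpoint of the gap and there are no violations; otherwise the
    threshold minimising misclassified pairs is chosen (pairs are called
    intra when value >= threshold; ties resolved toward the lower threshold).
    """
    missing = [g for g in matrix.labels if g not in labeling]
    if missing:
        raise ValueError(f"labeling missing genomes: {missing}")
    intra, inter = [], []
    for a, b, v in matrix.pair_values():
        if np.isnan(v):
            continue
        (intra if labeling[a] == labeling[b] else inter).append((a, b, v))
    if not intra or not inter:
        raise ValueError("need at least one intra- and one inter-genus pair")
    intra_v = np.array([v for *_, v in intra])
    inter_v = np.array([v for *_, v in inter])
    min_intra = float(intra_v.min())
    max_inter = float(inter_v.max())
    if max_inter < min_intra:
        threshold = (max_inter + min_intra) / 2.0
        n_violations = 0
    else:
        all_v = set(intra_v.tolist()) | set(inter_v.tolist())
        candidates = sorted(all_v) + [max(all_v) + 1.0]  # sentinel: all-inter call
        best_t, best_v = None, None
        for t in candidates:
            v = int((intra_v < t).sum() + (inter_v >= t).sum())
            if best_v is None or v < best_v:
                best_t, best_v = t, v
        threshold, n_violations = float(best_t), int(best_v)
    return ThresholdReport(
        index_kind=matrix.index_kind,
        intra_values=intra,
        inter_values=inter,
        min_intra=min_intra,
        max_inter=max_inter,
        threshold=threshold,
        n_violations=n_violations,
    )


def index_regression(matrix_x: SimilarityMatrix, matrix_y: SimilarityMatrix):
    """OLS of one index on another over shared lower-triangle pairs.

    Returns (slope, intercept, r_squared).  Requires identical label sets and
    at least three distinct pairs; raises on zero x-variance.
    """
    if set(matrix_x.labels) != set(matrix_y.labels):
        raise ValueError("matrices must cover the same genomes")
    pairs_y = {(a, b): v for a, b, v in matrix_y.pair_values()}
    xs, ys = [], []
    for a, b, v in matrix_x.pair_values():
        w = pairs_y.get((a, b), pairs_y.get((b, a)))
        if w is None or np.isnan(v) or np.isnan(w):
            continue
        xs.append(v)
        ys.append(w)
    if len(xs) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate regressor: zero variance in x")
    fit = linregress(xs, ys)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def classify_genome(
    genome_id: str,
    index_values: dict[str, dict[str, float]],
    reference_species: dict[str, str] | None = None,
    reference_genera: dict[str, str] | None = None,
    genus_thresholds: dict[str, float] = GENUS_THRESHOLDS,
    species_thresholds: dict[str, float] = SPECIES_THRESHOLDS,
    ssu_advisory: dict[str, float] = SSU_ADVISORY,
) -> TaxonomyAssignment:
    """Classify a query against references from its per-index best values.

    ``index_values`` maps index kind ("AAI"/"POCP"/"ANI"/"SSU") to
    {reference_id: value}.  AAI is the primary genus criterion; POCP and ANI
    corroborate, and disagreement among available verdicts yields
    ``genus_call="conflict"`` with every verdict listed.  A species is
    assigned only when ANI and AAI both clear their thresholds against the
    same reference.  16S identity is reported as advisory evidence only.
    """
    if not index_values or not any(index_values.values()):
        raise ValueError("empty reference set")
    reference_species = reference_species or {}
    reference_genera = reference_genera or {}
    evidence: list[str] = []
    best: dict[str, tuple[str, float]] = {}
    for kind, vals in index_values.items():
        if not vals:
            continue
        ref = max(sorted(vals), key=lambda r: vals[r])
        best[kind] = (ref, vals[ref])

    verdicts = {}
    for kind in ("AAI", "POCP", "ANI"):
        if kind in best and kind in genus_thresholds:
            ref, val = best[kind]
            verdicts[kind] = val >= genus_thresholds[kind]
            evidence.append(
                f"{kind} best {val:.1f} to {ref} vs genus threshold {genus_thresholds[kind]:.0f}"
            )
    if "SSU" in best:
        ref, val = best["SSU"]
        tag = "above" if val >= ssu_advisory["genus"] else "below"
        evidence.append(
            f"16S best {val:.1f} to {ref} {tag} advisory genus threshold "
            f"{ssu_advisory['genus']} (advisory only)"
        )

    if "AAI" not in verdicts:
        genus_call = "conflict"
        evidence.append("no AAI evidence; genus undecidable")
        nearest = best[next(iter(best))][0] if best else None
    else:
        nearest = best["AAI"][0]
        agreeing = all(verdicts.values())
        none_pass = not any(verdicts.values())
        if agreeing:
            genus = reference_genera.get(nearest, nearest)
            genus_call = f"assigned:{genus}"
        elif none_pass:
            genus_call = "novel_genus"
        else:
            genus_call = "conflict"
            evidence.append(f"discordant genus verdicts: {verdicts}")

    species_call = "n/a"
    if genus_call.startswith("assigned"):
        ani_ref = best.get("ANI", (None, None))[0]
        aai_ref = best.get("AAI", (None, None))[0]
        ani_ok = "ANI" in best and best["ANI"][1] >= species_thresholds["ANI"]
        aai_ok = "AAI" in best and best["AAI"][1] >= species_thresholds["AAI"]
        if ani_ok and aai_ok and ani_ref == aai_ref:
            species = reference_species.get(ani_ref, ani_ref)
            species_call = f"assigned:{species}"
            evidence.append(
                f"ANI {best['ANI'][1]:.1f} and AAI {best['AAI'][1]:.1f} to {ani_ref} "
                f"clear species thresholds {species_thresholds}"
            )
        else:
            species_call = "novel_species"
            evidence.append("genus assigned but species thresholds unmet")
    return TaxonomyAssignment(
        genome_id=genome_id,
        nearest_reference=nearest,
        best_values={k: v for k, (_, v) in best.items()},
        genus_call=genus_call,
        species_call=species_call,
        evidence=evidence,
    )
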