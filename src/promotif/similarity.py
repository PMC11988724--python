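"""Sequence-similarity covariates, gene-gene distances, and UPGMA trees.

Three related quantities feed the downstream statistics:

* per-gene motif similarity -- the mean Smith-Waterman score of each
  gene's binding-site sequences against the motif consensus, normalized to
  [0, 1] by the maximum attainable score (regression covariate);
* a gene-gene distance matrix -- 1 minus the Pearson correlation of the
  genes' plus-strand window-score profiles along the promoter;
* an average-linkage (UPGMA) tree over that distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .scanning import PWM, MotifHit, _BASE_INDEX


@dataclass
class AlignmentResult:
    """Optimal local alignment of two sequences (1-based inclusive bounds)."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str


@dataclass
class SimilarityRecord:
    gene_id: str
    tf_id: str
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [0, 1]")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < -1e-10).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclass
class TreeNode:
    """Rooted binary tree with leaf labels and ultrametric node heights."""

    height: float
    label: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.left.leaves() + self.right.leaves()

    def newick(self) -> str:
        return self._newick(parent_height=self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        branch = parent_height - self.height
        if self.is_leaf:
            return f"{self.label}:{branch:.6g}"
        inner = ",".join(
            c._newick(parent_height=self.height) for c in (self.left, self.right)
        )
        return f"({inner}):{branch:.6g}"

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Pairwise cophenetic distances (2 * height of the LCA)."""
        labels = sorted(self.leaves())
        idx = {lb: i for i, lb in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            lf = walk(node.left)
            rt = walk(node.right)
            for a in lf:
                for b in rt:
                    d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2 * node.height
            return lf + rt

        walk(self)
        return labels, d


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def sw_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with linear gap penalty.

    Among co-optimal alignments the one with the smallest ``a_end``, then
    smallest ``b_end``, is reported. Empty or completely dissimilar inputs
    yield score 0 with an empty aligned segment.
    """
    if match <= 0 or mismatch > 0 or gap >= 0:
        raise ValueError("require match > 0, mismatch <= 0, gap < 0")
    if not a or not b:
        return AlignmentResult(0.0, 0, 0, 0, 0, "", "")
    al = _aligner(match, mismatch, gap)
    score = float(al.score(a, b))
    if score <= 0:
        return AlignmentResult(0.0, 0, 0, 0, 0, "", "")
    alignments = al.align(a, b)
    best = None
    # cap the enumeration; co-optimal alignments can be combinatorial
    for i, aln in enumerate(alignments):
        c = aln.coordinates
        key = (int(c[0, -1]), int(c[1, -1]))
        if best is None or key < best[0]:
            best = (key, aln)
        if i >= 63:
            break
    aln = best[1]
    c = aln.coordinates
    return AlignmentResult(
        score=score,
        a_start=int(c[0, 0]) + 1,
        a_end=int(c[0, -1]),
        b_start=int(c[1, 0]) + 1,
        b_end=int(c[1, -1]),
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
    )


def gene_similarity(
    hits: list[MotifHit],
    consensus: str,
    gene_id: str | None = None,
    tf_id: str | None = None,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    aggregate: str = "mean",
) -> SimilarityRecord:
    """Per-gene similarity of viable binding-site sequences to the consensus.

    Each plus-strand hit contributes sw_score(matched_seq, consensus) /
    (match * L) in [0, 1]; the gene-level covariate is the mean (or, with
    ``aggregate='max'``, the maximum) over hits, and 0 for genes without
    viable hits.
    """
    if len(consensus) < 1:
        raise ValueError("consensus must be non-empty")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    viable = [h for h in hits if h.strand == "+"]
    gid = gene_id if gene_id is not None else (viable[0].gene_id if viable else "gene")
    tid = tf_id if tf_id is not None else (viable[0].tf_id if viable else "tf")
    if not viable:
        return SimilarityRecord(gene_id=gid, tf_id=tid, similarity=0.0)
    denom = match * len(consensus)
    sims = [
        min(sw_align(h.matched_seq, consensus, match, mismatch, gap).score / denom, 1.0)
        for h in viable
    ]
    value = float(np.mean(sims)) if aggregate == "mean" else float(max(sims))
    return SimilarityRecord(gene_id=gid, tf_id=tid, similarity=value)


def window_score_profile(pwm: PWM, promoter: str) -> np.ndarray:
    """Raw plus-strand log-odds score of every window along the promoter."""
    promoter = promoter.upper()
    L = pwm.length
    idx = np.array([_BASE_INDEX.get(b, -1) for b in promoter])
    cols = np.arange(L)
    out = np.empty(len(promoter) - L + 1)
    for start in range(len(out)):
        w = idx[start:start + L]
        out[start] = np.nan if (w < 0).any() else pwm.log_odds[w, cols].sum()
    return out


def profile_correlation_matrix(
    promoters: dict[str, str], pwm: PWM
) -> DistanceMatrix:
    """Gene-gene distances 1 - r from Pearson correlation of score profiles."""
    labels = list(promoters)
    lengths = {len(s) for s in promoters.values()}
    if len(lengths) != 1:
        raise ValueError("all promoters must have equal length")
    profiles = np.array([window_score_profile(pwm, promoters[g]) for g in labels])
    if np.isnan(profiles).any():
        bad = [labels[i] for i in np.unique(np.argwhere(np.isnan(profiles))[:, 0])]
        raise ValueError(f"N-containing windows break the profile for: {','.join(bad)}")
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance score profile for: {','.join(bad)}")
    r = np.corrcoef(profiles)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels=labels, matrix=d)


def upgma_tree(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Node height is half the merge distance, so cophenetic distances on an
    ultrametric input reproduce it exactly.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    # stable ordering so equal-distance merges resolve by label order
    order = np.argsort(np.array(d.labels, dtype=object))
    labels = [d.labels[i] for i in order]
    m = d.matrix[np.ix_(order, order)]
    Z = linkage(squareform(m, checks=False), method="average")
    root = to_tree(Z)

    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(height=0.0, label=labels[node.id])
        return TreeNode(
            height=node.dist / 2.0,
            left=convert(node.get_left()),
            right=convert(node.get_right()),
        )

    return convert(root)
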