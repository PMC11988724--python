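"""Synthetic study-condition generators.

Everything the pipeline consumes can be generated here with known ground
truth: promoter sets with motif occurrences planted at recorded positions
and strands, overdispersed count datasets with known regression
coefficients, and six-variable feature matrices with planted clusters.
Defaults mirror the study conditions: 1000-bp promoters, a per-site scan
p-value of 0.01, negative-binomial dispersion near 1.3, and four planted
clusters in six dimensions.

Every generator is a pure function of its configuration: the single seed
is fanned out into named sub-streams so the promoter, count and feature
generators do not perturb each other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .scanning import BASES, PFM, MotifHit, reverse_complement

#: cluster template: (center in R^6, isotropic spread, size)
ClusterSpec = tuple[np.ndarray, float, int]


def _default_clusters() -> list[ClusterSpec]:
    rng = np.random.default_rng(20240318)
    centers = rng.normal(0.0, 6.0, size=(4, 6))
    return [(centers[i], 1.0, 30) for i in range(4)]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 120
    promoter_length: int = 1000
    plant_rate: float = 2.0  # expected planted sites per promoter per factor
    minus_strand_fraction: float = 0.48
    distal_fraction: float = 0.25
    beta: np.ndarray = dc_field(
        default_factory=lambda: np.array([-0.8, 0.11, 4.3])
    )
    theta: float = 1.3  # NB dispersion; np.inf means Poisson
    cluster_spec: list[ClusterSpec] = dc_field(default_factory=_default_clusters)
    background: np.ndarray = dc_field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        for name in ("minus_strand_fraction", "distal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.plant_rate < 0:
            raise ValueError("plant_rate must be non-negative")
        if not self.theta > 0:
            raise ValueError("theta must be positive (np.inf for Poisson)")
        if self.n_genes < 0 or self.promoter_length < 1:
            raise ValueError("n_genes and promoter_length must be positive")
        for _, spread, size in self.cluster_spec:
            if size <= 0:
                raise ValueError("cluster sizes must be positive")
            if spread <= 0:
                raise ValueError("cluster spreads must be positive")

    def stream(self, name: str) -> np.random.Generator:
        """Named child RNG stream derived from the global seed."""
        key = zlib.crc32(name.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    planted_hits: list[MotifHit] = dc_field(default_factory=list)
    true_beta: np.ndarray | None = None
    true_theta: float | None = None
    true_labels: np.ndarray | None = None


def gen_pwm(length: int, seed: int = 0, sharpness: float = 1.0,
            depth: int = 100, motif_id: str = "synthetic_motif") -> PFM:
    """Generate a synthetic count matrix with controllable information content.

    ``sharpness`` in (0, 1] sets the consensus-base fraction per column
    (0.25 + 0.75 * sharpness of the column depth); sharpness 1 yields a
    degenerate matrix with a single allowed base per column.
    """
    if length < 4:
        raise ValueError("motif length must be at least 4")
    if not 0 < sharpness <= 1:
        raise ValueError("sharpness must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=length)
    counts = np.zeros((4, length), dtype=int)
    dom = int(round(depth * (0.25 + 0.75 * sharpness)))
    other, rem = divmod(depth - dom, 3)
    for j, c in enumerate(consensus):
        counts[:, j] = other
        counts[c, j] = dom + rem
    return PFM(counts=counts, motif_id=motif_id)


def gen_promoter_set(
    cfg: SimulationConfig, pwm: PFM, tf_id: str | None = None
) -> tuple[dict[str, str], GroundTruth]:
    """Random promoters with the motif consensus planted at known positions.

    Background bases are i.i.d. from ``cfg.background``. The number of
    plants per promoter is Poisson(plant_rate); each plant falls in the
    distal window [-1000, -750] with probability ``distal_fraction`` and
    on the minus strand with probability ``minus_strand_fraction`` (minus-
    strand plants insert the reverse complement of the consensus).
    Plants never overlap one another; positions that would overflow the
    promoter are redrawn.
    """
    L = pwm.length
    if cfg.promoter_length < L:
        raise ValueError("promoter_length must be at least the motif length")
    tf = tf_id if tf_id is not None else pwm.motif_id
    rng = cfg.stream(f"promoters:{tf}")
    consensus = pwm.consensus
    n = cfg.promoter_length
    distal_lo = max(0, n - 1000)          # array index of TSS-relative -1000
    distal_hi = n - 750                   # plants at index <= distal_hi are distal
    promoters: dict[str, str] = {}
    truth = GroundTruth()
    for g in range(cfg.n_genes):
        gene_id = f"G{g:04d}"
        seq = rng.choice(list(BASES), size=n, p=cfg.background)
        n_plants = rng.poisson(cfg.plant_rate)
        placed: list[tuple[int, int]] = []
        for _ in range(n_plants):
            for _attempt in range(200):
                if rng.random() < cfg.distal_fraction and distal_hi >= distal_lo:
                    start = int(rng.integers(distal_lo, min(distal_hi, n - L) + 1))
                else:
                    start = int(rng.integers(0, n - L + 1))
                if all(start + L <= s or start >= e for s, e in placed):
                    break
            else:  # promoter saturated; skip this plant
                continue
            strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
            word = consensus if strand == "+" else reverse_complement(consensus)
            seq[start:start + L] = list(word)
            placed.append((start, start + L))
            truth.planted_hits.append(
                MotifHit(gene_id=gene_id, tf_id=tf, position=start - n,
                         strand=strand, score=0.0, p_value=1.0,
                         matched_seq=word)
            )
        promoters[gene_id] = "".join(seq)
    # fill in the plus-strand context actually present in the sequence
    for h in truth.planted_hits:
        s = promoters[h.gene_id]
        idx = h.position + len(s)
        h.matched_seq = s[idx:idx + L]
    return promoters, truth


def gen_count_dataset(
    cfg: SimulationConfig, with_group: bool = False
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulated regression table: distal counts on plus-strand count and similarity.

    Predictors: ``plus_count`` ~ Poisson(5) small integers, ``similarity``
    ~ Beta(5, 2) in [0, 1], and optionally a binary ``group`` with its
    interaction with ``plus_count`` (design order: intercept, plus_count,
    similarity[, group, plus_count:group]). The response is NB2 with mean
    exp(X beta) and dispersion ``theta`` (Poisson when theta = inf).
    """
    p_expected = 5 if with_group else 3
    if len(cfg.beta) != p_expected:
        raise ValueError(f"beta must have length {p_expected}")
    rng = cfg.stream("counts")
    n = cfg.n_genes
    cols = ["plus_count", "similarity"] + (["group", "plus_count:group"]
                                           if with_group else [])
    if n == 0:
        empty = pd.DataFrame(columns=cols + ["distal_count"])
        return empty, GroundTruth(true_beta=np.asarray(cfg.beta),
                                  true_theta=cfg.theta)
    plus = rng.poisson(5.0, size=n)
    sim = rng.beta(5.0, 2.0, size=n)
    X = [np.ones(n), plus.astype(float), sim]
    data = {"plus_count": plus, "similarity": sim}
    if with_group:
        grp = rng.integers(0, 2, size=n)
        X += [grp.astype(float), (plus * grp).astype(float)]
        data["group"] = np.where(grp == 1, "GPCR-MetS", "oGPCR")
    with np.errstate(over="ignore"):
        mu = np.exp(np.column_stack(X) @ np.asarray(cfg.beta, float))
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite mean from the supplied beta")
    if np.isinf(cfg.theta):
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(cfg.theta, mu / cfg.theta))
    data["distal_count"] = y
    return pd.DataFrame(data), GroundTruth(true_beta=np.asarray(cfg.beta),
                                           true_theta=cfg.theta)


def gen_feature_matrix(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gaussian blobs around the configured centers in six dimensions."""
    if not cfg.cluster_spec:
        raise ValueError("cluster_spec must be non-empty")
    rng = cfg.stream("features")
    rows, labels = [], []
    for k, (center, spread, size) in enumerate(cfg.cluster_spec):
        center = np.asarray(center, float)
        if center.shape != (6,):
            raise ValueError("cluster centers must be 6-dimensional")
        rows.append(rng.normal(center, spread, size=(size, 6)))
        labels.extend([k] * size)
    X = np.vstack(rows)
    cols = ["klf14_dr", "srebf1_dr", "klf14_plus", "srebf1_plus",
            "klf14_sim", "srebf1_sim"]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "gene_id", [f"G{i:04d}" for i in range(len(df))])
    return df, GroundTruth(true_labels=np.array(labels))


def write_fasta(promoters: dict[str, str], path,
                metadata: pd.DataFrame | None = None) -> None:
    """FASTA with ``>gene|class=..|group=..`` headers when metadata is given."""
    meta = metadata.set_index("gene_id") if metadata is not None else None
    with open(path, "w") as fh:
        for gene, seq in promoters.items():
            header = gene
            if meta is not None and gene in meta.index:
                row = meta.loc[gene]
                header = f"{gene}|class={row['receptor_class']}|group={row['group']}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read promoters; parse class/group fields back out of the headers."""
    promoters: dict[str, str] = {}
    meta_rows = []
    name, chunks = None, []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln.startswith(">"):
                if name is not None:
                    promoters[name] = "".join(chunks)
                fields = ln[1:].split("|")
                name, chunks = fields[0], []
                kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
                meta_rows.append({"gene_id": name,
                                  "receptor_class": kv.get("class", "A"),
                                  "group": kv.get("group", "oGPCR")})
            elif ln:
                chunks.append(ln.upper())
    if name is not None:
        promoters[name] = "".join(chunks)
    return promoters, pd.DataFrame(meta_rows)
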