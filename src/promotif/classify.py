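"""Binding-site filtering, region classification, and count summaries.

The analysis keeps only "viable" hits -- those on the plus (5'->3')
strand -- before any association step. Each viable hit is flagged by
whether it falls in the distal promoter window (default [-1000, -750],
both endpoints inclusive, addressed by the hit's 5'-most base) and whether
its span overlaps an annotated enhancer or silencer interval by at least
one base. Summaries aggregate hits per receptor class and per gene into
the feature records used by clustering and regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .scanning import MotifHit

DISTAL_WINDOW = (-1000, -750)
DISTAL_BINS = ("1", "2", "3", "4", "5-10")


@dataclass
class RegionAnnotation:
    """Enhancer or silencer interval in TSS-relative coordinates."""

    gene_id: str
    region_type: str  # "enhancer" | "silencer"
    start: int  # inclusive, start <= end <= -1
    end: int

    def __post_init__(self) -> None:
        if self.region_type not in ("enhancer", "silencer"):
            raise ValueError("region_type must be 'enhancer' or 'silencer'")
        if not (-1000 <= self.start <= self.end <= -1):
            raise ValueError("interval must lie within [-1000, -1] with start <= end")


@dataclass
class RegionClassifiedHit:
    hit: MotifHit
    viable: bool
    distal: bool
    enhancer: bool
    silencer: bool


@dataclass
class GeneFeatureRecord:
    """Per-gene covariates: the six clustering/regression variables plus labels."""

    gene_id: str
    receptor_class: str = "A"  # A | B/Adhesion | C
    group: str = "oGPCR"  # oGPCR | GPCR-MetS
    tf_group: str = "none"  # A (KLF14 only) | B (SREBF-1 only) | C (both) | none
    klf14_dr: int = 0
    srebf1_dr: int = 0
    klf14_plus: int = 0
    srebf1_plus: int = 0
    klf14_sim: float = 0.0
    srebf1_sim: float = 0.0


KLF14 = "KLF14"
SREBF1 = "SREBF1"


def filter_viable(hits: list[MotifHit]) -> list[MotifHit]:
    """Keep plus-strand hits only, order preserved. Idempotent."""
    return [h for h in hits if h.strand == "+"]


def classify_hit(
    hit: MotifHit,
    annotations: list[RegionAnnotation] | None = None,
    distal_window: tuple[int, int] = DISTAL_WINDOW,
) -> RegionClassifiedHit:
    """Flag one hit by strand viability, distal window and annotations."""
    lo, hi = min(distal_window), max(distal_window)
    distal = lo <= hit.position <= hi
    span_end = hit.position + max(len(hit.matched_seq), 1) - 1
    enhancer = silencer = False
    for ann in annotations or []:
        if ann.gene_id != hit.gene_id:
            continue
        if ann.start <= span_end and hit.position <= ann.end:  # >= 1 bp overlap
            if ann.region_type == "enhancer":
                enhancer = True
            else:
                silencer = True
    return RegionClassifiedHit(
        hit=hit,
        viable=hit.strand == "+",
        distal=distal,
        enhancer=enhancer,
        silencer=silencer,
    )


def classify_hits(
    hits: list[MotifHit],
    annotations: list[RegionAnnotation] | None = None,
    known_genes: set[str] | None = None,
    distal_window: tuple[int, int] = DISTAL_WINDOW,
) -> list[RegionClassifiedHit]:
    anns = list(annotations or [])
    if known_genes is not None:
        unknown = {a.gene_id for a in anns} - known_genes
        if unknown:
            warnings.warn(f"annotations for unknown genes ignored: {sorted(unknown)}")
            anns = [a for a in anns if a.gene_id not in unknown]
    return [classify_hit(h, anns, distal_window) for h in hits]


def summarize_counts(
    classified: list[RegionClassifiedHit],
    metadata: pd.DataFrame,
    similarities: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate classified hits into class-level and gene-level tables.

    ``metadata`` needs columns gene_id, receptor_class, group; every hit's
    gene must appear in it. ``similarities`` (optional) carries gene_id,
    tf_id, similarity. Distal-region (DR) counts are computed over viable
    hits only, so per gene ``dr <= plus`` for each factor.

    Returns ``(count_summary, gene_features)``: the first indexed by
    (receptor_class, tf_id) with columns total/plus/minus/viable/
    silencer/enhancer/distal, the second one row per metadata gene.
    """
    meta = metadata.set_index("gene_id")
    hit_genes = {c.hit.gene_id for c in classified}
    missing = sorted(hit_genes - set(meta.index))
    if missing:
        raise ValueError(f"genes missing from metadata: {missing}")

    rows = pd.DataFrame(
        [
            {
                "gene_id": c.hit.gene_id,
                "tf_id": c.hit.tf_id,
                "strand": c.hit.strand,
                "viable": c.viable,
                "distal": c.distal,
                "enhancer": c.enhancer,
                "silencer": c.silencer,
            }
            for c in classified
        ]
    )
    if rows.empty:
        rows = pd.DataFrame(
            columns=["gene_id", "tf_id", "strand", "viable", "distal",
                     "enhancer", "silencer"]
        )
    rows = rows.merge(
        meta[["receptor_class"]], left_on="gene_id", right_index=True, how="left"
    )

    def _agg(g: pd.DataFrame) -> pd.Series:
        plus = int((g["strand"] == "+").sum())
        minus = int((g["strand"] == "-").sum())
        return pd.Series(
            {
                "total": len(g),
                "plus": plus,
                "minus": minus,
                "viable": plus,
                "silencer": int((g["viable"] & g["silencer"]).sum()),
                "enhancer": int((g["viable"] & g["enhancer"]).sum()),
                "distal": int((g["viable"] & g["distal"]).sum()),
            }
        )

    if rows.empty:
        summary = pd.DataFrame(
            columns=["total", "plus", "minus", "viable", "silencer", "enhancer",
                     "distal"]
        )
        summary.index = pd.MultiIndex.from_arrays([[], []],
                                                  names=["receptor_class", "tf_id"])
    else:
        summary = (
            rows.groupby(["receptor_class", "tf_id"])
            .apply(_agg, include_groups=False)
            .astype(int)
        )

    sim_lookup: dict[tuple[str, str], float] = {}
    if similarities is not None:
        for _, r in similarities.iterrows():
            sim_lookup[(r["gene_id"], r["tf_id"])] = float(r["similarity"])

    features = []
    for gene_id, mrow in meta.iterrows():
        g = rows[rows["gene_id"] == gene_id]
        klf_plus = int(((g["tf_id"] == KLF14) & (g["strand"] == "+")).sum())
        sre_plus = int(((g["tf_id"] == SREBF1) & (g["strand"] == "+")).sum())
        klf_dr = int(((g["tf_id"] == KLF14) & g["viable"] & g["distal"]).sum())
        sre_dr = int(((g["tf_id"] == SREBF1) & g["viable"] & g["distal"]).sum())
        if klf_plus and sre_plus:
            tf_group = "C"
        elif klf_plus:
            tf_group = "A"
        elif sre_plus:
            tf_group = "B"
        else:
            tf_group = "none"
        features.append(
            GeneFeatureRecord(
                gene_id=gene_id,
                receptor_class=str(mrow["receptor_class"]),
                group=str(mrow.get("group", "oGPCR")),
                tf_group=tf_group,
                klf14_dr=klf_dr,
                srebf1_dr=sre_dr,
                klf14_plus=klf_plus,
                srebf1_plus=sre_plus,
                klf14_sim=sim_lookup.get((gene_id, KLF14), 0.0),
                srebf1_sim=sim_lookup.get((gene_id, SREBF1), 0.0),
            )
        )
    gene_features = pd.DataFrame([f.__dict__ for f in features])
    return summary, gene_features


def bin_distal_counts(features: pd.DataFrame, tf: str = KLF14) -> pd.DataFrame:
    """Group genes by their distal-site count: categories 1, 2, 3, 4, 5-10.

    Genes with zero distal sites are omitted; counts above 10 fall in the
    open top category. Returns one row per (receptor_class, category) with
    the member genes, gene count and summed sites, plus per-class totals.
    """
    col = {KLF14: "klf14_dr", SREBF1: "srebf1_dr"}.get(tf, tf)
    if features.empty:
        return pd.DataFrame(
            columns=["receptor_class", "category", "genes", "n_genes", "n_sites"]
        )
    sub = features[features[col] > 0]
    out = []
    for cls, g in sub.groupby("receptor_class"):
        for cat in DISTAL_BINS:
            if cat == "5-10":
                sel = g[g[col] >= 5]
            else:
                sel = g[g[col] == int(cat)]
            if sel.empty:
                continue
            out.append(
                {
                    "receptor_class": cls,
                    "category": cat,
                    "genes": ",".join(sorted(sel["gene_id"])),
                    "n_genes": len(sel),
                    "n_sites": int(sel[col].sum()),
                }
            )
    return pd.DataFrame(out)


def read_bed_annotations(path, promoter_length: int = 1000) -> list[RegionAnnotation]:
    """Read enhancer/silencer intervals from BED in promoter-local coordinates.

    BED is 0-based half-open with 0 at position -promoter_length; the name
    column carries the region type. Converted to TSS-relative inclusive
    intervals.
    """
    anns = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            gene_id, start, end = parts[0], int(parts[1]), int(parts[2])
            region_type = parts[3] if len(parts) > 3 else "enhancer"
            anns.append(
                RegionAnnotation(
                    gene_id=gene_id,
                    region_type=region_type,
                    start=start - promoter_length,
                    end=end - 1 - promoter_length,
                )
            )
    return anns


def write_bed_annotations(anns: list[RegionAnnotation], path,
                          promoter_length: int = 1000) -> None:
    with open(path, "w") as fh:
        for a in anns:
            fh.write(
                f"{a.gene_id}\t{a.start + promoter_length}"
                f"\t{a.end + 1 + promoter_length}\t{a.region_type}\n"
            )
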