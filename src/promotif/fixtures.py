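"""Machine-readable encodings of the study's published count tables.

Three summaries are embedded: per-class binding-site totals (strand,
enhancer/silencer and distal-region marginals for receptor classes A,
B/Adhesion and C), the per-gene distal-region site counts behind them, and
the per-receptor site distribution for the metabolic-syndrome-associated
(GPCR-MetS) comparison set.

Because only marginals are printed, `load_paper_fixtures` also synthesizes
mock hit tables -- lists of `MotifHit` plus region annotations -- whose
strand/region marginals match the published numbers exactly (positions are
arbitrary within the implied windows), so the downstream summarizers can
be exercised end to end against the printed totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import KLF14, SREBF1, RegionAnnotation
from .scanning import MotifHit

MOCK_SEQ = "ACGTACGTAC"  # placeholder 10-mer carried by synthesized hits
_L = len(MOCK_SEQ)

#: per-class marginals: genes, total/plus/minus sites, silencer, enhancer, distal
TABLE1 = {
    "A": dict(n_genes=85, total=966, plus=501, minus=465,
              silencer=2, enhancer=64, distal=90),
    "B/Adhesion": dict(n_genes=33, total=520, plus=276, minus=244,
                       silencer=20, enhancer=34, distal=49),
    "C": dict(n_genes=8, total=103, plus=56, minus=47,
              silencer=0, enhancer=0, distal=11),
}

#: per-gene distal-region site counts (orphan receptors with >= 1 distal site)
TABLE2 = {
    "A": {
        "GPR21": 1, "GPR22": 1, "GPR25": 1, "GPR39": 1, "GPR50": 1,
        "GPR83": 1, "GPR84": 1, "GPR135": 1, "GPR142": 1, "GPR150": 1,
        "GPR153": 1, "GPR171": 1, "GPR183": 1, "MAS1L": 1,
        "GPR4": 2, "GPR19": 2, "GPR68": 2, "GPR132": 2, "GPR139": 2,
        "GPR182": 2, "MAS1": 2, "P2RY8": 2, "TAAR8": 2, "GPR55": 2,
        "GPR45": 3, "GPR78": 3, "LGR4": 3, "MRGPRD": 3, "MRGPRE": 3,
        "MRGPRG": 3,
        "GPR3": 4, "GPR17": 4, "GPR26": 4, "GPR176": 4, "P2RY10": 4,
        "GPR12": 8, "GPR37": 5, "GPR85": 5,
    },
    "B/Adhesion": {
        "ADGRD1": 1, "ADGRE1": 1, "ADGRF3": 1, "ADGRF5": 1, "ADGRL2": 1,
        "ADGRA1": 2, "CELSR3": 2, "ADGRG3": 2, "ADGRG6": 2, "ADGRL1": 2,
        "ADGRB1": 3, "ADGRB3": 3, "CELSR2": 3, "ADGRG5": 3,
        "ADGRB2": 4, "ADGRD2": 4, "ADGRG1": 4,
        "CELSR1": 5, "ADGRE2": 5,
    },
    "C": {
        "GPR56": 1, "GPR158": 1, "GPR179": 1, "GPRC5A": 1,
        "GPRC5C": 7,
    },
}

#: GPCR-MetS receptors: (#BS, #BS+, #BS-, #IR+, #BS-DR) per transcription factor
TABLE4 = {
    KLF14: {
        "LEPR": (50, 31, 19, 30, 1), "ADIPOR1": (6, 5, 1, 0, 1),
        "ADIPOR2": (1, 0, 1, 0, 0), "MC4R": (0, 0, 0, 0, 0),
        "GHSR": (17, 4, 13, 0, 1), "AGTR1": (2, 1, 1, 0, 0),
        "HTR2C": (12, 4, 8, 0, 1), "CNR1": (9, 2, 7, 0, 1),
        "MC3R": (4, 1, 3, 0, 0), "HRH1": (3, 1, 2, 0, 0),
        "HCRTR1": (27, 12, 15, 6, 8), "HCRTR2": (8, 2, 6, 0, 0),
        "FFAR3": (5, 2, 3, 0, 0), "S1PR1": (32, 23, 9, 0, 11),
        "S1PR2": (5, 3, 2, 0, 0), "FFAR1": (31, 8, 23, 0, 0),
        "HCAR2": (0, 0, 0, 0, 0), "P2RY6": (14, 6, 8, 0, 3),
    },
    SREBF1: {
        "LEPR": (1, 1, 0, 0, 1), "ADIPOR1": (1, 0, 1, 0, 0),
        "ADIPOR2": (3, 2, 1, 0, 0), "MC4R": (0, 0, 0, 0, 0),
        "GHSR": (4, 3, 1, 0, 0), "AGTR1": (5, 4, 1, 0, 1),
        "HTR2C": (4, 3, 1, 0, 0), "CNR1": (10, 6, 4, 0, 1),
        "MC3R": (3, 1, 2, 0, 0), "HRH1": (2, 2, 0, 0, 0),
        "HCRTR1": (3, 1, 2, 0, 0), "HCRTR2": (7, 4, 3, 0, 0),
        "FFAR3": (5, 4, 1, 0, 0), "S1PR1": (8, 2, 6, 0, 1),
        "S1PR2": (8, 4, 4, 0, 0), "FFAR1": (15, 9, 6, 0, 4),
        "HCAR2": (7, 6, 1, 0, 3), "P2RY6": (6, 3, 3, 0, 2),
    },
}


@dataclass
class PaperFixture:
    """Printed marginals plus marginal-consistent mock hit tables."""

    table1: pd.DataFrame
    table2: dict[str, dict[str, int]]
    table4: pd.DataFrame
    hits: list[MotifHit]
    annotations: list[RegionAnnotation]
    metadata: pd.DataFrame
    mets_hits: list[MotifHit]
    mets_annotations: list[RegionAnnotation]
    mets_metadata: pd.DataFrame

    def hits_for_class(self, receptor_class: str) -> list[MotifHit]:
        genes = set(
            self.metadata.loc[
                self.metadata["receptor_class"] == receptor_class, "gene_id"
            ]
        )
        return [h for h in self.hits if h.gene_id in genes]


def _mock_hit(gene: str, tf: str, position: int, strand: str) -> MotifHit:
    return MotifHit(gene_id=gene, tf_id=tf, position=position, strand=strand,
                    score=8.0, p_value=0.005, matched_seq=MOCK_SEQ)


def _class_gene_list(cls: str) -> list[str]:
    named = list(TABLE2[cls])
    n = TABLE1[cls]["n_genes"]
    tag = cls.split("/")[0]
    fillers = [f"OR{tag}_{i:02d}" for i in range(1, n - len(named) + 1)]
    return named + fillers


def _synthesize_class(cls: str) -> tuple[list[MotifHit], list[RegionAnnotation]]:
    spec = TABLE1[cls]
    genes = _class_gene_list(cls)
    hits: list[MotifHit] = []
    anns: list[RegionAnnotation] = []

    # distal plants, one block per gene inside [-1000, -750]
    for gene, count in TABLE2[cls].items():
        for k in range(count):
            hits.append(_mock_hit(gene, KLF14, -1000 + 6 * k, "+"))

    # enhancer / silencer hits inside per-gene annotated intervals
    def annotated(n: int, region: str, lo: int, hi: int, start_gene: int) -> None:
        gi = start_gene
        placed = 0
        while placed < n:
            gene = genes[gi % len(genes)]
            anns.append(RegionAnnotation(gene_id=gene, region_type=region,
                                         start=lo, end=hi))
            per_gene = min(3, n - placed)
            for k in range(per_gene):
                hits.append(_mock_hit(gene, KLF14, lo + 5 + 12 * k, "+"))
            placed += per_gene
            gi += 1

    annotated(spec["enhancer"], "enhancer", -420, -310, start_gene=0)
    annotated(spec["silencer"], "silencer", -260, -200, start_gene=len(genes) // 2)

    # remaining viable hits, proximal, clear of the annotated intervals
    rest = spec["plus"] - spec["distal"] - spec["enhancer"] - spec["silencer"]
    for i in range(rest):
        gene = genes[i % len(genes)]
        tf = KLF14 if i % 2 == 0 else SREBF1
        hits.append(_mock_hit(gene, tf, -11 - 3 * ((i // len(genes)) % 50), "+"))

    for i in range(spec["minus"]):
        gene = genes[i % len(genes)]
        tf = KLF14 if i % 2 == 0 else SREBF1
        hits.append(_mock_hit(gene, tf, -460 - 3 * ((i // len(genes)) % 90), "-"))
    return hits, anns


def _synthesize_mets() -> tuple[list[MotifHit], list[RegionAnnotation]]:
    hits: list[MotifHit] = []
    anns: list[RegionAnnotation] = []
    for tf, table in TABLE4.items():
        for gene, (total, plus, minus, ir_plus, dr) in table.items():
            assert plus + minus == total
            n_both = max(0, ir_plus + dr - plus)  # sites both distal and annotated
            dr_only = dr - n_both
            ir_only = ir_plus - n_both
            plain = plus - dr - ir_only
            if ir_plus:
                # one enhancer interval inside and one outside the distal window
                if n_both:
                    anns.append(RegionAnnotation(gene, "enhancer", -1000, -900))
                if ir_only:
                    anns.append(RegionAnnotation(gene, "enhancer", -420, -310))
            pos = 0
            for _ in range(n_both):
                hits.append(_mock_hit(gene, tf, -995 + 11 * pos, "+")); pos += 1
            pos = 0
            for _ in range(dr_only):
                hits.append(_mock_hit(gene, tf, -890 + 11 * pos, "+")); pos += 1
            pos = 0
            for _ in range(ir_only):
                hits.append(_mock_hit(gene, tf, -415 + 3 * pos, "+")); pos += 1
            pos = 0
            for _ in range(plain):
                hits.append(_mock_hit(gene, tf, -11 - 3 * pos, "+")); pos += 1
            pos = 0
            for _ in range(minus):
                hits.append(_mock_hit(gene, tf, -600 - 3 * pos, "-")); pos += 1
    return hits, anns


def load_paper_fixtures() -> PaperFixture:
    """Embedded published tables with marginal-consistent mock hit lists."""
    table1 = pd.DataFrame(TABLE1).T
    table1.index.name = "receptor_class"
    t4_rows = [
        {"tf_id": tf, "gene_id": g, "bs": v[0], "bs_plus": v[1],
         "bs_minus": v[2], "ir_plus": v[3], "bs_dr": v[4]}
        for tf, table in TABLE4.items() for g, v in table.items()
    ]
    table4 = pd.DataFrame(t4_rows)

    hits: list[MotifHit] = []
    anns: list[RegionAnnotation] = []
    meta_rows = []
    for cls in TABLE1:
        h, a = _synthesize_class(cls)
        hits.extend(h)
        anns.extend(a)
        for gene in _class_gene_list(cls):
            meta_rows.append(
                {"gene_id": gene, "receptor_class": cls, "group": "oGPCR"}
            )
    metadata = pd.DataFrame(meta_rows)

    mets_hits, mets_anns = _synthesize_mets()
    mets_metadata = pd.DataFrame(
        [{"gene_id": g, "receptor_class": "A", "group": "GPCR-MetS"}
         for g in TABLE4[KLF14]]
    )
    return PaperFixture(
        table1=table1,
        table2={cls: dict(v) for cls, v in TABLE2.items()},
        table4=table4,
        hits=hits,
        annotations=anns,
        metadata=metadata,
        mets_hits=mets_hits,
        mets_annotations=mets_anns,
        mets_metadata=mets_metadata,
    )
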