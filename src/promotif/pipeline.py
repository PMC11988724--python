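"""End-to-end orchestration: scan -> similarity -> classify -> cluster -> regress.

A single declarative configuration drives the stages in order, persists
every intermediate table as TSV, and emits a consolidated plain-text
report with a provenance block (config hash, seed). Identical inputs and
seed produce byte-identical outputs. ``fixture`` mode bypasses scanning
and feeds the published-table mock hits into classification so the
printed per-class marginals can be regenerated without external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (KLF14, SREBF1, bin_distal_counts, classify_hits,
                       filter_viable, read_bed_annotations, summarize_counts)
from .cluster import bootstrap_stability, pca, select_k, standardize
from .fixtures import load_paper_fixtures
from .regression import (ModelSpec, effects_table, fit_group_interaction,
                         fit_model, fit_poisson, overdispersion_test)
from .scanning import build_log_odds, parse_jaspar_pfm, scan_promoters
from .similarity import gene_similarity, profile_correlation_matrix, upgma_tree
from .simulate import SimulationConfig, gen_pwm, gen_promoter_set, read_fasta, \
    write_fasta

FEATURE_COLUMNS = ["klf14_dr", "srebf1_dr", "klf14_plus", "srebf1_plus",
                   "klf14_sim", "srebf1_sim"]


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | fixture | files
    out_dir: str = "promotif_out"
    seed: int = 0
    n_genes: int = 60
    fasta: str | None = None
    pfm_files: dict[str, str] = field(default_factory=dict)  # tf_id -> path
    bed: str | None = None
    metadata: str | None = None
    scan_pvalue: float = 0.01
    alignment_scores: tuple[float, float, float] = (2.0, -1.0, -2.0)
    distal_window: tuple[int, int] = (-1000, -750)
    kmax: int = 7
    n_clusters: int | None = None
    bootstrap_B: int = 100
    gap_B: int = 20
    family_policy: dict[str, str] = field(
        default_factory=lambda: {KLF14: "negbin", SREBF1: "poisson"}
    )
    run_tree: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.scan_pvalue <= 1:
            raise ValueError("scan p-value must lie in (0, 1]")
        if self.mode not in ("synthetic", "fixture", "files"):
            raise ValueError("mode must be synthetic, fixture or files")
        if self.mode == "files":
            for p in [self.fasta, *self.pfm_files.values()]:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"configured input missing: {p}")

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: PipelineConfig
    count_summary: pd.DataFrame
    gene_features: pd.DataFrame
    distal_bins: pd.DataFrame
    cluster_report: object | None = None
    stability: object | None = None
    pca_variance: np.ndarray | None = None
    regression_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    newick: str | None = None
    log: list[str] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"promotif {__version__} | seed={cfg.seed} "
                      f"| config={cfg.content_hash()}"]

    # ---- stage 1: inputs -------------------------------------------------
    if cfg.mode == "fixture":
        fx = load_paper_fixtures()
        hits, annotations, metadata = fx.hits, fx.annotations, fx.metadata
        promoters, pwms = {}, {}
        similarities = None
        log.append(f"fixture mode: {len(hits)} mock hits, "
                   f"{len(metadata)} genes")
    else:
        if cfg.mode == "synthetic":
            sim_cfg = SimulationConfig(seed=cfg.seed, n_genes=cfg.n_genes)
            pfms = {KLF14: gen_pwm(10, seed=cfg.seed, sharpness=0.9,
                                   motif_id=KLF14),
                    SREBF1: gen_pwm(10, seed=cfg.seed + 1, sharpness=0.9,
                                    motif_id=SREBF1)}
            promoters, _truth = gen_promoter_set(sim_cfg, pfms[KLF14],
                                                 tf_id=KLF14)
            rng = np.random.default_rng(cfg.seed)
            classes = rng.choice(["A", "B/Adhesion", "C"], size=cfg.n_genes,
                                 p=[0.68, 0.26, 0.06])
            groups = rng.choice(["oGPCR", "GPCR-MetS"], size=cfg.n_genes)
            metadata = pd.DataFrame({"gene_id": list(promoters),
                                     "receptor_class": classes,
                                     "group": groups})
            write_fasta(promoters, out / "promoters.fasta", metadata)
            for tf, pfm in pfms.items():
                (out / f"{tf}.pfm").write_text(pfm.to_jaspar())
            annotations = []
        else:
            promoters, metadata = read_fasta(cfg.fasta)
            if cfg.metadata:
                metadata = pd.read_csv(cfg.metadata, sep="\t")
            pfms = {tf: parse_jaspar_pfm(Path(p).read_text())
                    for tf, p in cfg.pfm_files.items()}
            annotations = (read_bed_annotations(cfg.bed) if cfg.bed else [])
        pwms = {tf: build_log_odds(pfm) for tf, pfm in pfms.items()}
        log.append(f"inputs: {len(promoters)} promoters, {len(pwms)} motifs")

        # ---- stage 2: scanning ------------------------------------------
        hits = []
        for tf, pwm in pwms.items():
            tf_hits = scan_promoters(pwm, promoters, alpha=cfg.scan_pvalue,
                                     tf_id=tf)
            log.append(f"scan {tf}: {len(tf_hits)} hits at p<={cfg.scan_pvalue}")
            hits.extend(tf_hits)

        # ---- stage 3: similarity ----------------------------------------
        match, mismatch, gap = cfg.alignment_scores
        sim_rows = []
        for tf, pwm in pwms.items():
            consensus = pwm.consensus
            for gene in promoters:
                gh = [h for h in hits if h.gene_id == gene and h.tf_id == tf]
                rec = gene_similarity(gh, consensus, gene_id=gene, tf_id=tf,
                                      match=match, mismatch=mismatch, gap=gap)
                sim_rows.append({"gene_id": gene, "tf_id": tf,
                                 "similarity": rec.similarity})
        similarities = pd.DataFrame(sim_rows)
        _write_tsv(similarities, out / "similarity.tsv")
        log.append(f"similarity: {len(similarities)} gene/factor records")

    hit_df = pd.DataFrame([h.__dict__ for h in hits])
    _write_tsv(hit_df, out / "hits.tsv")

    bundle_newick = None
    if cfg.mode != "fixture" and cfg.run_tree and len(promoters) >= 2:
        first_pwm = next(iter(pwms.values()))
        dm = profile_correlation_matrix(promoters, first_pwm)
        tree = upgma_tree(dm)
        bundle_newick = tree.newick()
        (out / "upgma.nwk").write_text(bundle_newick + "\n")
        _write_tsv(pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels),
                   out / "distance_matrix.tsv", index=True)

    # ---- stage 4: classification ----------------------------------------
    viable = filter_viable(hits)
    log.append(f"classification: {len(hits)} hits, {len(viable)} viable "
               f"(plus strand)")
    classified = classify_hits(hits, annotations,
                               known_genes=set(metadata["gene_id"]),
                               distal_window=cfg.distal_window)
    summary, features = summarize_counts(classified, metadata, similarities)
    distal_bins = bin_distal_counts(features, KLF14)
    _write_tsv(summary.reset_index(), out / "count_summary.tsv")
    _write_tsv(features, out / "gene_features.tsv")
    _write_tsv(distal_bins, out / "distal_bins.tsv")

    bundle = ReportBundle(config=cfg, count_summary=summary,
                          gene_features=features, distal_bins=distal_bins,
                          newick=bundle_newick, log=log)
    if cfg.mode == "fixture":
        _finish(bundle, out)
        return bundle

    # ---- stage 5: clustering --------------------------------------------
    Xdf = features[FEATURE_COLUMNS]
    varying = [c for c in FEATURE_COLUMNS if Xdf[c].nunique() > 1]
    if len(varying) >= 2 and len(features) > cfg.kmax:
        Z = standardize(Xdf[varying])
        report = select_k(Z, kmax=cfg.kmax, B_gap=cfg.gap_B, seed=cfg.seed)
        k_use = cfg.n_clusters or report.chosen_k
        k_use = max(k_use, 2)
        stab = bootstrap_stability(Z, k=k_use, B=cfg.bootstrap_B,
                                   seed=cfg.seed)
        pc = pca(Z, n_components=min(2, len(varying)))
        bundle.cluster_report = report
        bundle.stability = stab
        bundle.pca_variance = pc.variance_fraction
        ksel = pd.DataFrame({
            "k": report.ks,
            "wss": [report.wss[k] for k in report.ks],
            "silhouette": [report.silhouette.get(k, float("nan"))
                           for k in report.ks],
            "gap": [report.gap[k] for k in report.ks],
            "gap_se": [report.gap_se[k] for k in report.ks],
        })
        _write_tsv(ksel, out / "k_selection.tsv")
        _write_tsv(pd.DataFrame({
            "cluster": range(stab.k),
            "mean_jaccard": stab.mean_jaccard,
            "recovery_rate": stab.recovery_rate,
            "dissolution_rate": stab.dissolution_rate,
        }), out / "stability.tsv")
        log.append(f"clustering: votes={report.votes}, chosen K={k_use}")
    else:
        log.append("clustering skipped: insufficient variation or rows")

    # ---- stage 6: regression --------------------------------------------
    for tf, prefix in ((KLF14, "klf14"), (SREBF1, "srebf1")):
        fam = cfg.family_policy.get(tf, "poisson")
        spec = ModelSpec(response=f"{prefix}_dr",
                         predictors=[f"{prefix}_plus", f"{prefix}_sim"],
                         family=fam)
        try:
            fit = fit_model(features, spec)
            eff = effects_table(fit)
            bundle.regression_tables[tf] = eff
            _write_tsv(eff, out / f"regression_{prefix}.tsv")
            pois = fit_poisson(features, ModelSpec(
                response=spec.response, predictors=spec.predictors,
                family="poisson"))
            od = overdispersion_test(pois)
            log.append(
                f"regress {tf} ({fam}): deviance ratio {od.ratio:.3f} "
                f"(p={od.p_value:.3g})"
                + (f", theta={fit.theta:.3f}" if fit.theta else "")
            )
            if features["group"].nunique() > 1:
                gfit = fit_group_interaction(features, spec)
                geff = effects_table(gfit)
                bundle.regression_tables[f"{tf}:group"] = geff
                _write_tsv(geff, out / f"regression_{prefix}_group.tsv")
        except (ValueError, RuntimeError) as exc:
            log.append(f"regress {tf}: skipped ({exc})")

    _finish(bundle, out)
    return bundle


def _finish(bundle: ReportBundle, out: Path) -> None:
    lines = list(bundle.log)
    lines.append("")
    lines.append("count summary (per receptor class and factor):")
    lines.append(bundle.count_summary.to_string())
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("alignment_scores", "distal_window"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
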