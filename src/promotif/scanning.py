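"""Position-weight-matrix scanning of promoter sequences.

A JASPAR position frequency matrix (PFM) is turned into a log-odds
position weight matrix (PWM); a score threshold is calibrated to a target
per-site p-value from the exact score distribution under the background
model; both strands of each promoter are then scanned and hits reported in
TSS-relative coordinates (the promoter covers positions -1000..-1, with -1
adjacent to the transcription start site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PFM:
    """Position frequency matrix: base counts, rows in A,C,G,T order."""

    counts: np.ndarray  # (4, L) non-negative integers
    motif_id: str = "motif"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every PFM column needs at least one positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def to_jaspar(self) -> str:
        lines = [f">{self.motif_id} {self.motif_id}"]
        for i, b in enumerate(BASES):
            row = " ".join(str(int(c)) for c in self.counts[i])
            lines.append(f"{b} [ {row} ]")
        return "\n".join(lines) + "\n"


@dataclass
class PWM:
    """Log-odds matrix over a background base composition (log2 units)."""

    log_odds: np.ndarray  # (4, L)
    background: np.ndarray
    pseudocount: float
    motif_id: str = "motif"

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def score_word(self, word: str) -> float:
        if len(word) != self.length:
            raise ValueError("word length must equal motif length")
        return float(
            sum(self.log_odds[_BASE_INDEX[b], j] for j, b in enumerate(word))
        )


@dataclass
class ScoreDistribution:
    """Exact PWM score distribution on a discretized grid."""

    bin_width: float
    scores: np.ndarray  # ascending grid of attainable discretized scores
    pmf: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.pmf.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("score pmf must sum to 1")

    def tail(self, score: float) -> float:
        """P(discretized score >= score), clipped into (0, 1]."""
        # half-bin slack so a hit's own discretized score counts itself
        idx = np.searchsorted(self.scores, score - self.bin_width / 2)
        p = float(self.pmf[idx:].sum())
        return min(max(p, np.finfo(float).tiny), 1.0)


@dataclass
class MotifHit:
    """One predicted binding site in TSS-relative promoter coordinates.

    ``position`` addresses the 5'-most base of the site on the plus strand;
    a promoter of length 1000 spans positions -1000..-1.
    """

    gene_id: str
    tf_id: str
    position: int
    strand: str
    score: float
    p_value: float
    matched_seq: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


def parse_jaspar_pfm(text: str) -> PFM:
    """Parse one JASPAR-format PFM record (``>ID name`` + 4 labelled rows).

    Rows may appear in any order; they are re-sorted to A,C,G,T.
    """
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty PFM record")
    motif_id = "motif"
    if lines[0].startswith(">"):
        motif_id = lines[0][1:].split()[0] if lines[0][1:].split() else "motif"
        lines = lines[1:]
    rows: dict[str, list[int]] = {}
    for lineno, ln in enumerate(lines, start=2):
        parts = ln.replace("[", " ").replace("]", " ").split()
        if not parts or parts[0].upper() not in _BASE_INDEX:
            raise ValueError(f"line {lineno}: expected a base-labelled count row, got {ln!r}")
        base = parts[0].upper()
        try:
            vals = [int(float(v)) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric count in {ln!r}") from exc
        if any(v < 0 for v in vals):
            raise ValueError(f"line {lineno}: negative count")
        if base in rows:
            raise ValueError(f"line {lineno}: duplicate row for base {base}")
        rows[base] = vals
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ValueError(f"missing base rows: {','.join(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("ragged PFM rows: unequal lengths")
    counts = np.array([rows[b] for b in BASES], dtype=int)
    return PFM(counts=counts, motif_id=motif_id)


def build_log_odds(
    pfm: PFM,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
) -> PWM:
    """Build the log2-odds PWM.

    log_odds[b, j] = log2( (n[b,j] + pc*bg[b]) / (depth_j + pc) / bg[b] ),
    the standard Laplace-smoothed frequency over background ratio.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 strictly positive probabilities summing to 1")
    depth = pfm.counts.sum(axis=0).astype(float)
    if (depth <= 0).any():
        raise ValueError("zero-depth PFM column")
    freq = (pfm.counts + pseudocount * bg[:, None]) / (depth + pseudocount)
    log_odds = np.log2(freq / bg[:, None])
    return PWM(log_odds=log_odds, background=bg, pseudocount=pseudocount,
               motif_id=pfm.motif_id)


def _discretized_columns(pwm: PWM, bin_width: float) -> np.ndarray:
    """Per-column integer bin indices of the log-odds scores."""
    return np.rint(pwm.log_odds / bin_width).astype(np.int64)


def score_distribution(pwm: PWM, bin_width: float = 0.01) -> ScoreDistribution:
    """Exact distribution of the PWM score of a random background word.

    Column scores are rounded to a grid of width ``bin_width`` and the pmf
    of their sum is obtained by column-wise convolution, so tail
    probabilities are exact for the discretized score (grid error at most
    L*bin_width/2 in the score itself).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    cols = _discretized_columns(pwm, bin_width)
    lo = int(cols.min(axis=0).sum())
    hi = int(cols.max(axis=0).sum())
    pmf = np.zeros(hi - lo + 1)
    # running support [cur_lo, cur_lo + len - 1]
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.length):
        nxt = np.zeros(len(cur) + int(cols[:, j].max() - cols[:, j].min()))
        col_lo = int(cols[:, j].min())
        for b in range(4):
            off = int(cols[b, j]) - col_lo
            nxt[off:off + len(cur)] += pwm.background[b] * cur
        cur = nxt
        cur_lo += col_lo
    pmf[cur_lo - lo: cur_lo - lo + len(cur)] = cur
    scores = (np.arange(lo, hi + 1)) * bin_width
    keep = pmf > 0
    return ScoreDistribution(bin_width=bin_width, scores=scores[keep], pmf=pmf[keep])


def score_threshold_for_pvalue(
    pwm: PWM, alpha: float, bin_width: float = 0.01
) -> tuple[float, float, ScoreDistribution]:
    """Smallest discretized score t with P(score >= t) <= alpha.

    Returns ``(threshold, tail probability at threshold, distribution)``;
    with ``alpha = 1`` the threshold is the minimum attainable score.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    dist = score_distribution(pwm, bin_width)
    tails = np.cumsum(dist.pmf[::-1])[::-1]
    ok = tails <= alpha + 1e-12
    if ok.any():
        i = int(np.argmax(ok))
    else:  # alpha below the point mass of the best word: only the max passes
        i = len(dist.scores) - 1
    if alpha >= 1.0:
        i = 0
    return float(dist.scores[i]), float(tails[i]), dist


def scan_sequence(
    pwm: PWM,
    promoter: str,
    threshold: float,
    gene_id: str = "gene",
    tf_id: str | None = None,
    distribution: ScoreDistribution | None = None,
    bin_width: float = 0.01,
) -> list[MotifHit]:
    """Report every window on either strand scoring at least ``threshold``.

    Minus-strand hits are found on the reverse complement and mapped back
    to plus-strand coordinates of the window's 5'-most plus-strand base.
    Windows containing N are skipped. Hit p-values are tail probabilities
    from the exact background score distribution.
    """
    tf_id = tf_id if tf_id is not None else pwm.motif_id
    promoter = promoter.upper()
    L = pwm.length
    n = len(promoter)
    if n < L:
        warnings.warn(f"promoter shorter than motif ({n} < {L}); no windows scanned")
        return []
    if distribution is None:
        distribution = score_distribution(pwm, bin_width)
    # acceptance on the discretized scale keeps the hit rate consistent
    # with the exact distribution's tail probability at the threshold
    bw = distribution.bin_width
    thr_bin = int(np.rint(threshold / bw))
    seq_idx = np.array([_BASE_INDEX.get(b, -1) for b in promoter])
    hits: list[MotifHit] = []
    for strand in "+-":
        idx = seq_idx if strand == "+" else np.array(
            [_BASE_INDEX.get(b, -1) for b in reverse_complement(promoter)]
        )
        for start in range(n - L + 1):
            window = idx[start:start + L]
            if (window < 0).any():  # contains N
                continue
            score = float(pwm.log_odds[window, np.arange(L)].sum())
            if int(np.rint(score / bw)) < thr_bin:
                continue
            if strand == "+":
                plus_start = start
                seq = promoter[start:start + L]
            else:
                plus_start = n - start - L
                seq = promoter[plus_start:plus_start + L]
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    tf_id=tf_id,
                    position=plus_start - n,
                    strand=strand,
                    score=score,
                    p_value=distribution.tail(score),
                    matched_seq=seq,
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_promoters(
    pwm: PWM,
    promoters: dict[str, str],
    alpha: float = 0.01,
    bin_width: float = 0.01,
    tf_id: str | None = None,
) -> list[MotifHit]:
    """Calibrate the threshold once and scan a promoter collection."""
    threshold, _, dist = score_threshold_for_pvalue(pwm, alpha, bin_width)
    hits: list[MotifHit] = []
    for gene_id, seq in promoters.items():
        hits.extend(
            scan_sequence(pwm, seq, threshold, gene_id=gene_id, tf_id=tf_id,
                          distribution=dist)
        )
    return hits
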