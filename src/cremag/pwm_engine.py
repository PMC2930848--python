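"""Position weight matrices and promoter scanning.

A position frequency matrix (PFM, base counts per motif column) is turned
into a log-odds position weight matrix (PWM) against a uniform 0.25
background with a per-column pseudocount (default ``sqrt`` of the column
total).  Window scores are reported on the relative-score scale

    rel = 100 * (raw - min_score) / (max_score - min_score)

where ``min_score``/``max_score`` are the sums of column minima/maxima, so a
consensus word scores 100 and the worst word scores 0.  ``N`` bases take the
column-minimum weight (worst case) and so can only lower a score.

Scanning covers both strands; reverse-strand matches are reported at the
forward-orientation offset of the matched footprint.  Score accumulation is
performed column-by-column in ascending order so that vectorized scanning is
bit-identical to a naive per-window sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .promoter_model import PromoterSequence, reverse_complement

__all__ = [
    "PFM",
    "PWM",
    "TFBSHit",
    "pfm_to_pwm",
    "relative_score",
    "scan",
    "scan_all",
    "encode_sequence",
    "hits_to_bed",
    "SCORE_EPS",
]

# absolute tolerance used on the 0-100 relative-score scale when comparing a
# floating-point score against an integer threshold
SCORE_EPS = 1e-9

_BASES = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.uint8)  # everything unknown -> 4 ('N')
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 (uint8)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 4 x L nonnegative counts, rows A,C,G,T."""

    id: str
    name: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"{self.id}: counts must be 4 x L with L >= 1")
        if (counts < 0).any():
            raise ValueError(f"{self.id}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.id}: zero-total column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log-odds weight matrix with its score range and information content."""

    id: str
    name: str
    weights: np.ndarray          # 4 x L log2 odds
    min_score: float             # sum of column minima
    max_score: float             # sum of column maxima
    info_content: float          # bits

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    @property
    def extended_weights(self) -> np.ndarray:
        """5 x L weights where row 4 ('N') carries the column minimum."""
        return np.vstack([self.weights, self.weights.min(axis=0)])

    @property
    def degenerate(self) -> bool:
        return self.max_score == self.min_score


def pfm_to_pwm(pfm: PFM, pseudocount: str | float = "sqrt") -> PWM:
    """Log-odds transform against a uniform background.

    Per column with total ``N`` and pseudocount ``p`` (``sqrt`` rule:
    ``p = sqrt(N)``; a float gives a fixed pseudocount)::

        weight[b] = log2( (count[b] + 0.25 p) / (N + p) / 0.25 )

    Information content is ``sum_i (2 + sum_b q log2 q)`` bits over the
    smoothed column frequencies ``q``.
    """
    counts = pfm.counts
    totals = counts.sum(axis=0)
    if isinstance(pseudocount, str):
        if pseudocount != "sqrt":
            raise ValueError(f"unknown pseudocount rule {pseudocount!r}")
        p = np.sqrt(totals)
    else:
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        p = np.full_like(totals, float(pseudocount))
    freqs = (counts + 0.25 * p) / (totals + p)
    if (freqs <= 0).any():
        raise ValueError(
            f"{pfm.id}: zero frequency with zero pseudocount; "
            "use a positive pseudocount"
        )
    weights = np.log2(freqs / 0.25)
    info = float(np.sum(2.0 + (freqs * np.log2(freqs)).sum(axis=0)))
    return PWM(
        id=pfm.id,
        name=pfm.name,
        weights=weights,
        min_score=float(weights.min(axis=0).sum()),
        max_score=float(weights.max(axis=0).sum()),
        info_content=info,
    )


@dataclass(frozen=True)
class TFBSHit:
    """One matrix match inside a promoter window.

    ``offset`` indexes the hit's first base in promoter orientation;
    ``strand`` is the match strand relative to the promoter ('+' = same as
    the transcript).  ``conservation`` is the mean per-base conservation over
    the footprint; ``coding`` is True when any footprint base is exonic.
    """

    matrix_id: str
    gene_id: str
    tss_index: int
    offset: int
    strand: str
    length: int
    rel_score: float
    conservation: float
    coding: bool


def _window_raw_scores(ext_weights: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Raw log-odds score of every window, accumulated column-by-column in
    ascending order (bit-identical to a naive left-to-right sum)."""
    L = ext_weights.shape[1]
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.float64)
    scores = np.zeros(n, dtype=np.float64)
    for i in range(L):
        scores += ext_weights[enc[i : i + n], i]
    return scores


def _rel_from_raw(pwm: PWM, raw: np.ndarray) -> np.ndarray:
    if pwm.degenerate:
        return np.full_like(raw, 100.0)
    return 100.0 * (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)


def relative_score(pwm: PWM, window: str) -> float:
    """Relative score (0-100 %) of a single L-mer against the matrix."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != matrix width {pwm.width}")
    if pwm.degenerate:
        warnings.warn(f"{pwm.id}: degenerate matrix (min == max); "
                      "relative score defined as 100", stacklevel=2)
        return 100.0
    enc = encode_sequence(window)
    raw = 0.0
    ext = pwm.extended_weights
    for i in range(pwm.width):
        raw += ext[enc[i], i]
    return 100.0 * (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)


def scan(
    pwm: PWM,
    promoter: PromoterSequence,
    threshold_pct: float,
    *,
    matrix_id: str | None = None,
) -> list[TFBSHit]:
    """All matrix matches on both strands with relative score >= threshold.

    Reverse-strand matches are reported at the promoter-orientation offset of
    the matched footprint.  A promoter shorter than the matrix yields no
    hits.  Ties at exactly the threshold are included.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold_pct must be in [0, 100]")
    mat_id = matrix_id if matrix_id is not None else pwm.id
    L = pwm.width
    n = len(promoter.seq)
    if n < L:
        return []
    ext = pwm.extended_weights
    cons = promoter.conservation
    cons_cum = np.concatenate([[0.0], np.cumsum(cons)])
    mask = promoter.coding_mask
    mask_cum = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])

    hits: list[tuple[int, str, float]] = []
    enc_fwd = encode_sequence(promoter.seq)
    rel_fwd = _rel_from_raw(pwm, _window_raw_scores(ext, enc_fwd))
    for off in np.nonzero(rel_fwd >= threshold_pct - SCORE_EPS)[0]:
        hits.append((int(off), "+", float(rel_fwd[off])))

    enc_rev = encode_sequence(reverse_complement(promoter.seq))
    rel_rev = _rel_from_raw(pwm, _window_raw_scores(ext, enc_rev))
    for j in np.nonzero(rel_rev >= threshold_pct - SCORE_EPS)[0]:
        hits.append((n - L - int(j), "-", float(rel_rev[j])))

    hits.sort(key=lambda h: (h[0], h[1]))
    out = []
    for off, strand, rel in hits:
        footprint_cons = (cons_cum[off + L] - cons_cum[off]) / L
        coding = bool(mask_cum[off + L] - mask_cum[off] > 0)
        out.append(
            TFBSHit(
                matrix_id=mat_id,
                gene_id=promoter.tss.gene_id,
                tss_index=promoter.tss.tss_index,
                offset=off,
                strand=strand,
                length=L,
                rel_score=rel,
                conservation=float(footprint_cons),
                coding=coding,
            )
        )
    return out


def scan_all(
    pwms: list[PWM],
    promoters: list[PromoterSequence],
    thresholds: dict[str, float] | float,
) -> dict[tuple[str, str, int], list[TFBSHit]]:
    """Batch scan: hit lists keyed by (matrix_id, gene_id, tss_index).

    ``thresholds`` is a per-matrix mapping or one shared percentage.  Output
    ordering is deterministic: matrix id, then gene id, then TSS index, then
    offset within each list.
    """
    store: dict[tuple[str, str, int], list[TFBSHit]] = {}
    for pwm in sorted(pwms, key=lambda m: m.id):
        t = thresholds[pwm.id] if isinstance(thresholds, dict) else thresholds
        for prom in sorted(promoters,
                           key=lambda p: (p.tss.gene_id, p.tss.tss_index)):
            key = (pwm.id, prom.tss.gene_id, prom.tss.tss_index)
            store[key] = scan(pwm, prom, t)
    return store


def hits_to_bed(hits: list[TFBSHit]) -> list[tuple]:
    """BED6 rows for hits: chrom column = gene|tss, score = rel score x 10."""
    return [
        (
            f"{h.gene_id}|{h.tss_index}",
            h.offset,
            h.offset + h.length,
            h.matrix_id,
            round(h.rel_score * 10),
            h.strand,
        )
        for h in hits
    ]
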