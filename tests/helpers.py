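"""Independent brute-force oracles and small builders shared across tests.

The oracles deliberately avoid the vectorized code paths they check: scores
are accumulated per window in plain Python, islands are found by explicit
frame enumeration, and frequency tables by literal re-scanning.
"""

from __future__ import annotations

import numpy as np

from cremag.promoter_model import PromoterSequence, TSSRecord, reverse_complement
from cremag.pwm_engine import PWM, SCORE_EPS

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def promoter_from_seq(
    seq: str,
    conservation: np.ndarray | None = None,
    coding_mask: np.ndarray | None = None,
    gene_id: str = "G",
    tss_index: int = 0,
    strand: str = "+",
) -> PromoterSequence:
    """Wrap a bare sequence as a promoter window (TSS at index 0)."""
    n = len(seq)
    return PromoterSequence(
        tss=TSSRecord(gene_id=gene_id, chrom="chrT", strand=strand,
                      position=0, tss_index=tss_index),
        seq=seq,
        conservation=(np.zeros(n) if conservation is None
                      else np.asarray(conservation, dtype=float)),
        coding_mask=(np.zeros(n, dtype=bool) if coding_mask is None
                     else np.asarray(coding_mask, dtype=bool)),
        upstream_len=0,
        downstream_len=n,
        window_start=0,
        window_end=n,
    )


def naive_window_rel(pwm: PWM, window: str) -> float:
    """Per-window relative score by explicit left-to-right accumulation."""
    ext = pwm.extended_weights
    raw = 0.0
    for i, ch in enumerate(window):
        raw += ext[_IDX[ch], i]
    if pwm.max_score == pwm.min_score:
        return 100.0
    return 100.0 * (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)


def naive_all_scores(pwm: PWM, seq: str) -> list[tuple[int, str, float]]:
    """(offset, strand, relative score) of every window on both strands,
    reverse-strand windows reported at forward-orientation offsets."""
    L = pwm.width
    out = []
    for off in range(len(seq) - L + 1):
        out.append((off, "+", naive_window_rel(pwm, seq[off : off + L])))
    rc = reverse_complement(seq)
    for j in range(len(seq) - L + 1):
        out.append((len(seq) - L - j, "-", naive_window_rel(pwm, rc[j : j + L])))
    return out


def naive_hits(pwm: PWM, seq: str, threshold: float,
               scores: list[tuple[int, str, float]] | None = None
               ) -> list[tuple[int, str, float]]:
    scores = naive_all_scores(pwm, seq) if scores is None else scores
    return sorted((o, s, r) for o, s, r in scores if r >= threshold - SCORE_EPS)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def naive_islands(seq: str, frame: int = 200, step: int = 1,
                  min_len: int = 200, gc_min: float = 50.0,
                  oe_min: float = 0.6) -> list[tuple[int, int]]:
    """Frame-enumeration island finder: (start, end) of merged regions whose
    aggregate stats still pass."""
    from cremag.cpg import window_stats

    marks = []
    for s in range(0, len(seq) - frame + 1, step):
        sub = seq[s : s + frame]
        n_c, n_g = sub.count("C"), sub.count("G")
        n_cg = sum(1 for i in range(frame - 1)
                   if sub[i] == "C" and sub[i + 1] == "G")
        gc = 100.0 * (n_c + n_g) / frame
        oe = (n_cg * frame) / (n_c * n_g) if n_c and n_g else 0.0
        if gc > gc_min and oe > oe_min:
            marks.append(s)
    regions = []
    for s in marks:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = s + frame
        else:
            regions.append([s, s + frame])
    out = []
    for s, e in regions:
        if e - s <= min_len:
            continue
        gc, oe = window_stats(seq[s:e])
        if gc > gc_min and oe > oe_min:
            out.append((s, e))
    return out
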