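"""Background sequence models and per-matrix score-threshold calibration.

Three background types estimate how often a matrix matches by chance:

``random``
    i.i.d. uniform A/C/G/T sequence (20 Mbp at production scale).
``core``
    the 200 bp immediately 5' of every gene start, oriented and
    concatenated in annotation order.
``conserved``
    maximal runs of bases with conservation strictly above a cutoff
    (default 0.75) inside every gene's promoter window, concatenated.

Each background is scanned once per matrix at threshold 60 %; hits are
bucketed by the floor of their relative score, giving the both-strand hit
rate per Mbp at every integer threshold 60..100 in a single pass.  The
optimized threshold for a matrix is the integer threshold whose background
rate is closest to the user's tolerated random-occurrence rate, ties going
to the higher (more restrictive) threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ConservationTrack, GenomeAnnotation
from .promoter_model import TSSRecord, extract_promoter, reverse_complement
from .pwm_engine import (
    PWM,
    SCORE_EPS,
    _rel_from_raw,
    _window_raw_scores,
    encode_sequence,
)

__all__ = [
    "BackgroundFrequencyTable",
    "generate_random_background",
    "build_core_background",
    "build_conserved_background",
    "compute_frequency_table",
    "optimize_threshold",
    "THRESHOLD_MIN",
    "THRESHOLD_MAX",
]

THRESHOLD_MIN = 60
THRESHOLD_MAX = 100
THRESHOLDS = tuple(range(THRESHOLD_MIN, THRESHOLD_MAX + 1))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class BackgroundFrequencyTable:
    """Per-matrix hit rates (hits per Mbp, both strands) at integer
    thresholds 60..100 for one background type."""

    background_type: str
    total_length: int
    freq: dict[tuple[str, int], float] = field(default_factory=dict)

    def matrices(self) -> list[str]:
        return sorted({m for m, _ in self.freq})

    def get(self, matrix_id: str, threshold: int) -> float:
        return self.freq[(matrix_id, threshold)]

    def check_monotone(self) -> None:
        for m in self.matrices():
            rates = [self.freq[(m, t)] for t in THRESHOLDS]
            if any(a < b for a, b in zip(rates, rates[1:])):
                raise AssertionError(f"{m}: frequency not non-increasing in threshold")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#matrix_id\tthreshold\thits_per_Mbp\tbackground_type"
                     "\ttotal_length\n")
            for m in self.matrices():
                for t in THRESHOLDS:
                    fh.write(f"{m}\t{t}\t{self.freq[(m, t)]:.10g}\t"
                             f"{self.background_type}\t{self.total_length}\n")

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundFrequencyTable":
        freq: dict[tuple[str, int], float] = {}
        bg_type, total = None, None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                m, t, f, b, n = line.rstrip("\n").split("\t")
                freq[(m, int(t))] = float(f)
                bg_type, total = b, int(n)
        if bg_type is None:
            raise ValueError(f"{path}: empty frequency table")
        return cls(background_type=bg_type, total_length=total, freq=freq)


def generate_random_background(length_bp: int, seed) -> str:
    """i.i.d. uniform A/C/G/T sequence from a seeded generator.

    Production scale is 20 Mbp; tests scale the length down.
    """
    if length_bp < 1000:
        raise ValueError("background length must be >= 1000 bp")
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, 4, size=length_bp)
    return _BASES[draw].tobytes().decode("ascii")


def build_core_background(annotation: GenomeAnnotation,
                          genome: dict[str, str],
                          window: int = 200) -> str:
    """Concatenated, oriented 200-bp windows immediately 5' of every gene
    start, in annotation order (truncated at chromosome edges)."""
    parts = []
    for gene in annotation:
        chrom_seq = genome[gene.chrom]
        gs = gene.gene_start
        if gene.strand == "+":
            seg = chrom_seq[max(0, gs - window):gs]
        else:
            seg = reverse_complement(chrom_seq[gs + 1:gs + 1 + window])
        parts.append(seg)
    return "".join(parts)


def build_conserved_background(
    genome: dict[str, str],
    conservation: ConservationTrack,
    annotation: GenomeAnnotation,
    cutoff: float = 0.75,
    upstream_len: int = 10000,
    downstream_len: int = 5000,
) -> str:
    """Concatenated maximal runs of bases with conservation strictly above
    ``cutoff`` inside each gene's promoter window (taken around the gene
    start, i.e. the 5'-most TSS)."""
    parts = []
    for gene in annotation:
        tss = TSSRecord(gene_id=gene.gene_id, chrom=gene.chrom,
                        strand=gene.strand, position=gene.gene_start)
        prom = extract_promoter(genome, conservation, GenomeAnnotation(genes=[]),
                                tss, upstream_len, downstream_len)
        above = prom.conservation > cutoff
        if not above.any():
            continue
        # maximal runs of True
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            parts.append(prom.seq[s:e])
    return "".join(parts)


def _bucketed_counts(pwm: PWM, enc: np.ndarray) -> np.ndarray:
    """Hit counts per integer threshold 60..100 for one strand of one
    sequence, via floor-of-score bucketing."""
    rel = _rel_from_raw(pwm, _window_raw_scores(pwm.extended_weights, enc))
    if rel.size == 0:
        return np.zeros(len(THRESHOLDS), dtype=np.int64)
    floors = np.floor(rel + SCORE_EPS).astype(np.int64)
    floors = floors[floors >= THRESHOLD_MIN]
    np.clip(floors, THRESHOLD_MIN, THRESHOLD_MAX, out=floors)
    hist = np.bincount(floors - THRESHOLD_MIN, minlength=len(THRESHOLDS))
    # hits with floor >= t, i.e. reverse cumulative sum
    return hist[::-1].cumsum()[::-1]


def compute_frequency_table(
    background: str,
    pwms: list[PWM],
    background_type: str = "random",
) -> BackgroundFrequencyTable:
    """Single-pass both-strand frequency table over one background sequence.

    Equivalent to rescanning at every integer threshold separately, but each
    window is scored once and assigned to the bucket of its floored relative
    score.
    """
    if len(background) < 1000:
        raise ValueError("background must be >= 1000 bp")
    widest = max(p.width for p in pwms)
    if len(background) < widest:
        raise ValueError("background shorter than the widest matrix")
    mbp = len(background) / 1e6
    enc_fwd = encode_sequence(background)
    enc_rev = encode_sequence(reverse_complement(background))
    table = BackgroundFrequencyTable(background_type=background_type,
                                     total_length=len(background))
    for pwm in pwms:
        counts = _bucketed_counts(pwm, enc_fwd) + _bucketed_counts(pwm, enc_rev)
        for t, c in zip(THRESHOLDS, counts):
            table.freq[(pwm.id, t)] = float(c) / mbp
    return table


def optimize_threshold(
    table: BackgroundFrequencyTable, matrix_id: str, target_freq: float
) -> int:
    """Integer threshold whose background rate is closest to ``target_freq``
    (hits/Mbp); exact-distance ties go to the higher threshold."""
    if (matrix_id, THRESHOLD_MIN) not in table.freq:
        raise KeyError(f"matrix {matrix_id} absent from frequency table")
    best_t, best_d = THRESHOLD_MIN, None
    for t in THRESHOLDS:
        d = abs(table.freq[(matrix_id, t)] - target_freq)
        if best_d is None or d <= best_d:
            best_t, best_d = t, d
    return best_t
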