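"""CpG island detection by the classic sliding-frame criteria.

An island is a region longer than 200 bp whose G+C content exceeds 50 % and
whose observed/expected CpG dinucleotide ratio exceeds 0.6 (all three
inequalities strict).  Detection slides a 200-bp frame (1-bp step by
default) across the island window — 5 kb upstream to 10 kb downstream of a
TSS, the mirror image of the promoter scan window — marks qualifying
frames, merges overlapping qualifying footprints, and keeps merged regions
whose own aggregate statistics still pass.

``N`` bases count toward frame length but not toward the G/C/CG tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeAnnotation
from .promoter_model import TSSRecord, extract_promoter

__all__ = [
    "CpGIsland",
    "window_stats",
    "detect_islands",
    "tss_island_summary",
    "genome_island_stats",
    "extract_island_window",
    "islands_to_bed",
    "ISLAND_UPSTREAM",
    "ISLAND_DOWNSTREAM",
]

# island search window around a TSS (oriented): note the asymmetry is the
# mirror image of the 10 kb up / 5 kb down promoter scan window
ISLAND_UPSTREAM = 5000
ISLAND_DOWNSTREAM = 10000


@dataclass(frozen=True)
class CpGIsland:
    """One detected island, in oriented island-window coordinates."""

    start: int
    end: int
    gc_pct: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _base_counts(seq: str) -> tuple[int, int, int]:
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")  # str.count is non-overlapping; CG cannot overlap itself
    return n_c, n_g, n_cg


def window_stats(seq: str) -> tuple[float, float]:
    """(%GC, observed/expected CpG ratio) of one sequence.

    ``obs/exp = N_CG * L / (N_C * N_G)``, defined as 0 when the sequence has
    no C or no G.
    """
    L = len(seq)
    if L < 2:
        raise ValueError("window_stats requires a sequence of length >= 2")
    n_c, n_g, n_cg = _base_counts(seq)
    gc_pct = 100.0 * (n_c + n_g) / L
    obs_exp = (n_cg * L) / (n_c * n_g) if n_c and n_g else 0.0
    return gc_pct, obs_exp


def detect_islands(
    seq: str,
    frame: int = 200,
    step: int = 1,
    min_len: int = 200,
    gc_min: float = 50.0,
    oe_min: float = 0.6,
) -> list[CpGIsland]:
    """Islands in one oriented island-window sequence.

    Frames of ``frame`` bp are marked when %GC > ``gc_min`` AND obs/exp >
    ``oe_min`` (strict); overlapping qualifying frames merge by footprint
    union; a merged region survives only if its length exceeds ``min_len``
    and its own aggregate statistics still pass both thresholds.
    """
    L = len(seq)
    if L < frame:
        return []
    enc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (enc == ord("C")).astype(np.int64)
    is_g = (enc == ord("G")).astype(np.int64)
    cg_start = np.zeros(L, dtype=np.int64)
    if L >= 2:
        cg_start[:-1] = ((enc[:-1] == ord("C")) & (enc[1:] == ord("G"))).astype(np.int64)

    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(cg_start)])

    starts = np.arange(0, L - frame + 1, step)
    n_c = cum_c[starts + frame] - cum_c[starts]
    n_g = cum_g[starts + frame] - cum_g[starts]
    # CG dinucleotides fully inside the frame: start positions in [s, s+frame-1)
    n_cg = cum_cg[starts + frame - 1] - cum_cg[starts]

    gc_pct = 100.0 * (n_c + n_g) / frame
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(
            (n_c > 0) & (n_g > 0), n_cg * frame / np.maximum(n_c * n_g, 1), 0.0
        )
    qualifying = (gc_pct > gc_min) & (obs_exp > oe_min)

    islands: list[CpGIsland] = []
    q_idx = np.nonzero(qualifying)[0]
    if q_idx.size == 0:
        return islands
    # merge overlapping qualifying footprints [s, s + frame)
    region_start = int(starts[q_idx[0]])
    region_end = region_start + frame
    regions: list[tuple[int, int]] = []
    for i in q_idx[1:]:
        s = int(starts[i])
        if s <= region_end:  # footprints overlap or touch
            region_end = s + frame
        else:
            regions.append((region_start, region_end))
            region_start, region_end = s, s + frame
    regions.append((region_start, region_end))

    for s, e in regions:
        if e - s <= min_len:
            continue
        gc, oe = window_stats(seq[s:e])
        if gc > gc_min and oe > oe_min:
            islands.append(CpGIsland(start=s, end=e, gc_pct=gc, obs_exp=oe))
    return islands


def extract_island_window(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    tss: TSSRecord,
    upstream: int = ISLAND_UPSTREAM,
    downstream: int = ISLAND_DOWNSTREAM,
) -> str:
    """Oriented island-window sequence (5 kb up / 10 kb down by default)."""
    prom = extract_promoter(genome, None, GenomeAnnotation(genes=[]),
                            tss, upstream, downstream)
    return prom.seq


def tss_island_summary(islands: list[CpGIsland]) -> int:
    """Total island length (bp) overlapping one TSS's island window."""
    return sum(isl.length for isl in islands)


def annotate_tss_with_islands(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    tss_records: dict[str, list[TSSRecord]],
    step: int = 1,
) -> dict[str, list[TSSRecord]]:
    """Fill ``cpg_island_total_len`` on every TSS record."""
    from dataclasses import replace

    out: dict[str, list[TSSRecord]] = {}
    for gene_id, records in tss_records.items():
        filled = []
        for r in records:
            seq = extract_island_window(genome, annotation, r)
            total = tss_island_summary(detect_islands(seq, step=step))
            filled.append(replace(r, cpg_island_total_len=total))
        out[gene_id] = filled
    return out


def genome_island_stats(per_gene_island_len: dict[str, int]) -> tuple[float, float]:
    """(mean, sample sd) of total island length per gene, genome-wide.

    Genes without islands contribute 0, keeping the query/genome comparison
    on the same per-gene scale.
    """
    if len(per_gene_island_len) < 2:
        raise ValueError("genome island statistics require at least 2 genes")
    values = np.array(list(per_gene_island_len.values()), dtype=float)
    return float(values.mean()), float(values.std(ddof=1))


def islands_to_bed(gene_id: str, tss_index: int,
                   islands: list[CpGIsland]) -> list[tuple]:
    """BED4 rows with %GC and obs/exp appended as extra columns."""
    return [
        (f"{gene_id}|{tss_index}", isl.start, isl.end,
         f"{gene_id}|{tss_index}", f"{isl.gc_pct:.2f}", f"{isl.obs_exp:.3f}")
        for isl in islands
    ]
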