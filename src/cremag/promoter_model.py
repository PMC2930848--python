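"""Strand-oriented promoter windows around transcription start sites.

A gene's transcripts are collapsed to distinct TSS positions; each TSS can
be refined against CAGE tag clusters (experimentally observed 5' ends) and
annotated with a promoter-strength TPM.  Promoter windows are extracted in
transcript orientation: index 0 is the most upstream base, index
``upstream_len`` is the TSS base itself, and increasing index always means
downstream, regardless of genomic strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import (
    CAGETagClusterSet,
    ConservationTrack,
    GenomeAnnotation,
)

__all__ = [
    "TSSRecord",
    "PromoterSequence",
    "cluster_tss",
    "remap_tss_with_cage",
    "extract_promoter",
    "select_tss",
    "tss_to_bed",
]

NO_CAGE_TPM = -1.0  # sentinel: no CAGE cluster within range of this TSS

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TSSRecord:
    """One transcription start site of a gene.

    ``tpm`` is the maximum normalized CAGE tag count (tags per million)
    across tissues, or -1 when no cluster supports the site.
    ``cpg_island_total_len`` is filled in by the CpG-island module.
    """

    gene_id: str
    chrom: str
    strand: str
    position: int
    tss_index: int = 0
    tpm: float = NO_CAGE_TPM
    cpg_island_total_len: int = 0
    transcript_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.tpm < 0 and self.tpm != NO_CAGE_TPM:
            raise ValueError("tpm must be >= 0 or exactly -1")


@dataclass
class PromoterSequence:
    """Oriented window ``[-upstream_len, +downstream_len)`` around a TSS.

    ``seq``, ``conservation`` and ``coding_mask`` all have identical length
    and orientation (increasing index = downstream).  Minus-strand windows
    are reverse-complemented.  ``upstream_len``/``downstream_len`` are the
    realized lengths after truncation at chromosome edges;
    ``truncated_upstream``/``truncated_downstream`` record how many bases
    were lost.  ``window_start``/``window_end`` are the genomic bounds.
    """

    tss: TSSRecord
    seq: str
    conservation: np.ndarray
    coding_mask: np.ndarray
    upstream_len: int
    downstream_len: int
    window_start: int
    window_end: int
    truncated_upstream: int = 0
    truncated_downstream: int = 0

    def __post_init__(self):
        n = len(self.seq)
        if len(self.conservation) != n or len(self.coding_mask) != n:
            raise ValueError("seq, conservation and coding_mask lengths differ")
        if self.upstream_len + self.downstream_len != n:
            raise ValueError("window lengths inconsistent with sequence length")

    def __len__(self) -> int:
        return len(self.seq)

    def genomic_span(self, offset: int, length: int) -> tuple[int, int]:
        """Genomic [start, end) of the footprint at oriented ``offset``."""
        if self.tss.strand == "+":
            start = self.window_start + offset
        else:
            start = self.window_end - offset - length
        return start, start + length

    def offset_to_tss_relative(self, offset: int) -> int:
        """Oriented offset converted to a TSS-relative coordinate
        (negative = upstream of the TSS)."""
        return offset - self.upstream_len


def cluster_tss(annotation: GenomeAnnotation) -> dict[str, list[TSSRecord]]:
    """Collapse each gene's transcripts into distinct TSS records.

    Transcripts sharing a start position form one record; records are indexed
    in 5'→3' gene orientation (index 0 = most distal, i.e. 5'-most).
    """
    out: dict[str, list[TSSRecord]] = {}
    for gene in annotation:
        groups: dict[int, list[str]] = {}
        for tx in gene.transcripts:
            pos = tx.start if gene.strand == "+" else tx.end - 1
            groups.setdefault(pos, []).append(tx.transcript_id)
        ordered = sorted(groups) if gene.strand == "+" else sorted(groups, reverse=True)
        out[gene.gene_id] = [
            TSSRecord(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                position=pos,
                tss_index=i,
                transcript_ids=tuple(sorted(groups[pos])),
            )
            for i, pos in enumerate(ordered)
        ]
    return out


def _cluster_distance(position: int, start: int, end: int) -> int:
    """Minimum absolute distance from a base to the cluster interval
    (0 when the base lies inside)."""
    if start <= position < end:
        return 0
    return min(abs(position - start), abs(position - (end - 1)))


def remap_tss_with_cage(
    tss: TSSRecord, clusters: CAGETagClusterSet, max_distance: int = 200
) -> TSSRecord:
    """Refine a TSS against same-strand CAGE tag clusters.

    The closest cluster within ``max_distance`` bp wins (ties by total tag
    count); the TSS moves to the in-cluster position with the highest tag
    count (ties to the most 5' position in gene orientation) and ``tpm``
    becomes the cluster's maximum per-tissue TPM.  With no cluster in range
    the position is kept and ``tpm`` is set to the -1 sentinel.
    """
    candidates = clusters.on(tss.chrom, tss.strand)
    best = None
    best_key = None
    for cl in candidates:
        d = _cluster_distance(tss.position, cl.start, cl.end)
        if d > max_distance:
            continue
        key = (d, -cl.total_tags)
        if best_key is None or key < best_key:
            best, best_key = cl, key
    if best is None:
        return replace(tss, tpm=NO_CAGE_TPM)
    counts = np.asarray(best.counts)
    top = counts.max()
    peak_offsets = np.nonzero(counts == top)[0]
    # tie among equal peak counts: most 5' position in gene orientation
    off = peak_offsets.min() if tss.strand == "+" else peak_offsets.max()
    return replace(tss, position=best.start + int(off), tpm=best.max_tpm)


def _coding_mask_for_window(
    annotation: GenomeAnnotation, chrom: str, start: int, end: int
) -> np.ndarray:
    """True where a base of genomic ``[start, end)`` overlaps any exon of any
    transcript of any gene (UTRs included)."""
    mask = np.zeros(end - start, dtype=bool)
    for gene in annotation:
        if gene.chrom != chrom:
            continue
        for tx in gene.transcripts:
            if tx.end <= start or tx.start >= end:
                continue
            for es, ee in tx.exons:
                lo, hi = max(es, start), min(ee, end)
                if lo < hi:
                    mask[lo - start : hi - start] = True
    return mask


def extract_promoter(
    genome: dict[str, str],
    conservation: ConservationTrack | None,
    annotation: GenomeAnnotation,
    tss: TSSRecord,
    upstream_len: int,
    downstream_len: int,
) -> PromoterSequence:
    """Extract the oriented promoter window around a TSS.

    On '+' the genomic window is ``[pos - upstream, pos + downstream)``;
    on '-' it is ``[pos - downstream + 1, pos + upstream + 1)`` and the
    window is reverse-complemented so the TSS base sits at oriented index
    ``upstream_len``.  Windows are truncated (never padded) at chromosome
    edges.
    """
    if tss.chrom not in genome:
        raise KeyError(f"TSS {tss.gene_id}/{tss.tss_index}: chromosome "
                       f"{tss.chrom} not in genome")
    chrom_seq = genome[tss.chrom]
    chrom_len = len(chrom_seq)
    if not 0 <= tss.position < chrom_len:
        raise ValueError(
            f"TSS {tss.gene_id}/{tss.tss_index}: position {tss.position} "
            f"outside chromosome {tss.chrom}"
        )
    if tss.strand == "+":
        want_start = tss.position - upstream_len
        want_end = tss.position + downstream_len
    else:
        want_start = tss.position - downstream_len + 1
        want_end = tss.position + upstream_len + 1
    start = max(0, want_start)
    end = min(chrom_len, want_end)
    lost_left = start - want_start
    lost_right = want_end - end

    seq = chrom_seq[start:end]
    if conservation is not None and tss.chrom in conservation:
        cons = np.array(conservation[tss.chrom][start:end], dtype=np.float64)
    else:
        cons = np.zeros(end - start, dtype=np.float64)
    mask = _coding_mask_for_window(annotation, tss.chrom, start, end)

    if tss.strand == "+":
        up = upstream_len - lost_left
        down = downstream_len - lost_right
        trunc_up, trunc_down = lost_left, lost_right
    else:
        seq = reverse_complement(seq)
        cons = cons[::-1].copy()
        mask = mask[::-1].copy()
        up = upstream_len - lost_right
        down = downstream_len - lost_left
        trunc_up, trunc_down = lost_right, lost_left

    return PromoterSequence(
        tss=tss,
        seq=seq,
        conservation=cons,
        coding_mask=mask,
        upstream_len=up,
        downstream_len=down,
        window_start=start,
        window_end=end,
        truncated_upstream=trunc_up,
        truncated_downstream=trunc_down,
    )


def select_tss(records: list[TSSRecord], mode: str) -> list[TSSRecord]:
    """Apply one of the five alternative-TSS selection modes.

    ``all`` keeps everything; ``most_distal`` keeps the single 5'-most TSS in
    gene orientation; ``highest_tpm`` keeps the TSS with maximum TPM (the -1
    sentinel ranks below any real value; if every record carries the sentinel
    the selection falls back to ``most_distal`` with a warning);
    ``with_cpg``/``without_cpg`` partition on overlap with a CpG island.
    """
    if not records:
        return []
    strand = records[0].strand
    if any(r.gene_id != records[0].gene_id for r in records):
        raise ValueError("select_tss expects records from a single gene")

    def most_distal(recs: list[TSSRecord]) -> TSSRecord:
        if strand == "+":
            return min(recs, key=lambda r: r.position)
        # 5'-most on '-' is the largest coordinate; tie-break to the smallest
        # genomic coordinate is vacuous once positions are distinct
        return max(recs, key=lambda r: r.position)

    if mode == "all":
        return list(records)
    if mode == "most_distal":
        return [most_distal(records)]
    if mode == "highest_tpm":
        if all(r.tpm == NO_CAGE_TPM for r in records):
            warnings.warn(
                f"{records[0].gene_id}: no CAGE support on any TSS; "
                "falling back to the most distal TSS",
                stacklevel=2,
            )
            return [most_distal(records)]
        top = max(r.tpm for r in records)
        tied = [r for r in records if r.tpm == top]
        return [most_distal(tied)]
    if mode == "with_cpg":
        return [r for r in records if r.cpg_island_total_len > 0]
    if mode == "without_cpg":
        return [r for r in records if r.cpg_island_total_len == 0]
    raise ValueError(f"unknown tss_mode {mode!r}")


def tss_to_bed(records: list[TSSRecord]) -> list[tuple]:
    """BED6 rows for selected TSSs (name = gene|index, -1 TPM encoded as
    score 0 with a ``noCAGE`` flag in the name)."""
    rows = []
    for r in records:
        flag = "" if r.tpm != NO_CAGE_TPM else "|noCAGE"
        score = 0 if r.tpm == NO_CAGE_TPM else round(r.tpm)
        rows.append((r.chrom, r.position, r.position + 1,
                     f"{r.gene_id}|{r.tss_index}{flag}", score, r.strand))
    return rows
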