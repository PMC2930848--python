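"""Readers and writers for the external formats the engine touches.

All genomic coordinates throughout the package are 0-based, half-open
``[start, end)``.  Sequences are uppercase strings over ``{A, C, G, T, N}``.

The tab-delimited dialects are fixed and documented here:

annotation (8 columns, header line starting with ``#`` optional)
    gene_id, transcript_id, chrom, strand, tx_start, tx_end,
    exon_starts (comma-separated), exon_ends (comma-separated)

conservation
    either triplet lines ``chrom <TAB> pos <TAB> score`` (bases not listed
    carry score 0), or a ``fixedStep chrom=<c> start=<s> step=1`` header
    followed by one score per line (start is 0-based, unlike UCSC wiggle)

CAGE tag clusters (6 columns)
    chrom, strand, start, end, per-position tag counts (comma-separated,
    one per base of the cluster), per-tissue TPM values
    (comma-separated ``tissue:value`` pairs)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Transcript",
    "GeneRecord",
    "GenomeAnnotation",
    "ConservationTrack",
    "CAGECluster",
    "CAGETagClusterSet",
    "RunConfig",
    "read_genome",
    "write_genome",
    "read_jaspar_pfms",
    "write_jaspar_pfms",
    "read_annotation",
    "write_annotation",
    "read_conservation",
    "write_conservation",
    "read_cage_clusters",
    "write_cage_clusters",
    "read_gene_list",
    "write_gene_list",
    "write_bed",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into ``{chrom: uppercase sequence}``.

    Record ids are the first whitespace-delimited token of the header.
    Raises :class:`FormatError` on an empty file, a file that does not start
    with a FASTA header, or characters outside ``{A, C, G, T, N}``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                )
            break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    genome: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id}: invalid characters {sorted(bad)}"
                )
            genome[rec.id] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices

_PFM_ROW_ORDER = "ACGT"


def read_jaspar_pfms(path: str | Path) -> list:
    """Parse JASPAR-style PFM text into a list of :class:`cremag.pwm_engine.PFM`.

    Each record is a header line ``>ID name`` followed by four labelled count
    rows in the order A, C, G, T, optionally bracketed JASPAR-2016 style::

        >MA0001.1 AGL3
        A  [ 0  3 79 40 ... ]
        C  [94 75  4  3 ... ]
        ...
    """
    from .pwm_engine import PFM

    path = Path(path)
    pfms: list[PFM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {i + 1}: expected '>' header")
        header = line[1:].split(None, 1)
        if not header:
            raise FormatError(f"{path}: line {i + 1}: empty matrix header")
        mat_id = header[0]
        mat_name = header[1].strip() if len(header) > 1 else mat_id
        rows: dict[str, list[float]] = {}
        i += 1
        for base in _PFM_ROW_ORDER:
            if i >= n:
                raise FormatError(f"{path}: matrix {mat_id}: missing row {base}")
            row = lines[i].strip()
            if not row or row[0].upper() != base:
                raise FormatError(
                    f"{path}: matrix {mat_id}: expected count row for {base}, "
                    f"got {row[:30]!r}"
                )
            payload = row[1:].replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in payload.split()]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: matrix {mat_id}: bad count in row {base}: {exc}"
                ) from None
            if any(v < 0 for v in values):
                raise FormatError(
                    f"{path}: matrix {mat_id}: negative count in row {base}"
                )
            rows[base] = values
            i += 1
        widths = {len(rows[b]) for b in _PFM_ROW_ORDER}
        if len(widths) != 1 or widths == {0}:
            raise FormatError(
                f"{path}: matrix {mat_id}: row lengths differ "
                f"({[len(rows[b]) for b in _PFM_ROW_ORDER]})"
            )
        counts = np.array([rows[b] for b in _PFM_ROW_ORDER], dtype=float)
        pfms.append(PFM(id=mat_id, name=mat_name, counts=counts))
    if not pfms:
        raise FormatError(f"{path}: no PFM records found")
    return pfms


def write_jaspar_pfms(pfms: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.id} {pfm.name}\n")
            for bi, base in enumerate(_PFM_ROW_ORDER):
                vals = " ".join(f"{v:g}" for v in pfm.counts[bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# gene annotation


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.transcript_id}: end <= start")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.transcript_id}: exon [{s},{e}) outside transcript "
                    f"bounds [{self.start},{self.end})"
                )


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: no transcripts")

    @property
    def gene_start(self) -> int:
        """Genomic coordinate of the 5'-most base of the gene in gene orientation."""
        if self.strand == "+":
            return min(t.start for t in self.transcripts)
        return max(t.end for t in self.transcripts) - 1

    def tss_positions(self) -> list[int]:
        """Distinct transcript-start base coordinates (genomic)."""
        if self.strand == "+":
            return sorted({t.start for t in self.transcripts})
        return sorted({t.end - 1 for t in self.transcripts})


@dataclass
class GenomeAnnotation:
    genes: list[GeneRecord]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


def _parse_int_list(tok: str) -> list[int]:
    tok = tok.strip().rstrip(",")
    return [int(t) for t in tok.split(",")] if tok else []


def read_annotation(path: str | Path) -> GenomeAnnotation:
    path = Path(path)
    per_gene: dict[str, list[Transcript]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 8:
                raise FormatError(
                    f"{path}: line {lineno}: expected 8 tab-delimited columns, got {len(cols)}"
                )
            gene_id, tx_id, chrom, strand, tx_start, tx_end, ex_s, ex_e = cols
            starts, ends = _parse_int_list(ex_s), _parse_int_list(ex_e)
            if len(starts) != len(ends):
                raise FormatError(
                    f"{path}: line {lineno} ({tx_id}): exon start/end count mismatch"
                )
            try:
                tx = Transcript(
                    transcript_id=tx_id,
                    start=int(tx_start),
                    end=int(tx_end),
                    exons=tuple(zip(starts, ends)),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if gene_id in meta and meta[gene_id] != (chrom, strand):
                raise FormatError(
                    f"{path}: line {lineno}: gene {gene_id} changes chrom/strand"
                )
            meta[gene_id] = (chrom, strand)
            per_gene.setdefault(gene_id, []).append(tx)
    genes = []
    for gene_id, txs in per_gene.items():
        chrom, strand = meta[gene_id]
        try:
            genes.append(
                GeneRecord(gene_id=gene_id, chrom=chrom, strand=strand,
                           transcripts=tuple(txs))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: gene {gene_id}: {exc}") from None
    return GenomeAnnotation(genes=genes)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\ttranscript_id\tchrom\tstrand\ttx_start\ttx_end"
                 "\texon_starts\texon_ends\n")
        for gene in annotation:
            for tx in gene.transcripts:
                ex_s = ",".join(str(s) for s, _ in tx.exons)
                ex_e = ",".join(str(e) for _, e in tx.exons)
                fh.write(
                    f"{gene.gene_id}\t{tx.transcript_id}\t{gene.chrom}\t"
                    f"{gene.strand}\t{tx.start}\t{tx.end}\t{ex_s}\t{ex_e}\n"
                )


# ---------------------------------------------------------------------------
# conservation track


class ConservationTrack:
    """Per-chromosome arrays of per-base conservation probabilities in [0, 1].

    Bases not covered by the source file carry score 0.
    """

    def __init__(self, scores: dict[str, np.ndarray]):
        self.scores: dict[str, np.ndarray] = {}
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValueError(f"{chrom}: conservation scores outside [0, 1]")
            self.scores[chrom] = arr

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.scores[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.scores

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConservationTrack):
            return NotImplemented
        return self.scores.keys() == other.scores.keys() and all(
            np.allclose(self.scores[c], other.scores[c]) for c in self.scores
        )


def read_conservation(
    path: str | Path, chrom_lengths: dict[str, int]
) -> ConservationTrack:
    """Read the triplet or fixed-step conservation dialect.

    ``chrom_lengths`` defines the full extent of every chromosome; unlisted
    bases get score 0.
    """
    path = Path(path)
    arrays = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}

    def _check(chrom, pos, score, lineno):
        if chrom not in arrays:
            raise FormatError(f"{path}: line {lineno}: unknown chromosome {chrom}")
        if not (0 <= pos < len(arrays[chrom])):
            raise FormatError(
                f"{path}: line {lineno}: position {pos} outside chromosome "
                f"{chrom} (length {len(arrays[chrom])})"
            )
        if not (0.0 <= score <= 1.0):
            raise FormatError(
                f"{path}: line {lineno}: score {score} outside [0, 1]"
            )

    fixed_chrom: str | None = None
    fixed_pos = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                if kv.get("step", "1") != "1":
                    raise FormatError(f"{path}: line {lineno}: only step=1 supported")
                fixed_chrom = kv["chrom"]
                fixed_pos = int(kv["start"])
                if fixed_chrom not in arrays:
                    raise FormatError(
                        f"{path}: line {lineno}: unknown chromosome {fixed_chrom}"
                    )
                continue
            cols = line.split("\t")
            if len(cols) == 1 and fixed_chrom is not None:
                score = float(cols[0])
                _check(fixed_chrom, fixed_pos, score, lineno)
                arrays[fixed_chrom][fixed_pos] = score
                fixed_pos += 1
            elif len(cols) == 3:
                chrom, pos, score = cols[0], int(cols[1]), float(cols[2])
                _check(chrom, pos, score, lineno)
                arrays[chrom][pos] = score
            else:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'chrom<TAB>pos<TAB>score' "
                    "or a fixedStep block"
                )
    return ConservationTrack(arrays)


def write_conservation(track: ConservationTrack, path: str | Path,
                       precision: int = 4) -> None:
    """Write nonzero positions in the triplet dialect (zeros are implicit)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tscore\n")
        for chrom in track.scores:
            arr = track.scores[chrom]
            for pos in np.nonzero(arr)[0]:
                fh.write(f"{chrom}\t{pos}\t{round(float(arr[pos]), precision):g}\n")


# ---------------------------------------------------------------------------
# CAGE tag clusters


@dataclass(frozen=True)
class CAGECluster:
    chrom: str
    strand: str
    start: int
    end: int
    counts: tuple[int, ...]   # one per base of [start, end)
    tpm: tuple[tuple[str, float], ...]  # (tissue, TPM)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("cluster end must exceed start")
        if len(self.counts) != self.end - self.start:
            raise ValueError("one tag count per cluster base required")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative tag count")

    @property
    def total_tags(self) -> int:
        return sum(self.counts)

    @property
    def max_tpm(self) -> float:
        return max(v for _, v in self.tpm) if self.tpm else 0.0


@dataclass
class CAGETagClusterSet:
    clusters: list[CAGECluster]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)

    def on(self, chrom: str, strand: str) -> list[CAGECluster]:
        return [c for c in self.clusters if c.chrom == chrom and c.strand == strand]


def read_cage_clusters(path: str | Path,
                       chrom_lengths: dict[str, int] | None = None
                       ) -> CAGETagClusterSet:
    path = Path(path)
    clusters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(cols)}"
                )
            chrom, strand, start, end, counts_tok, tpm_tok = cols
            counts = tuple(_parse_int_list(counts_tok))
            tpm = []
            for pair in tpm_tok.split(","):
                pair = pair.strip()
                if not pair:
                    continue
                tissue, _, val = pair.partition(":")
                tpm.append((tissue, float(val)))
            try:
                cl = CAGECluster(chrom=chrom, strand=strand, start=int(start),
                                 end=int(end), counts=counts, tpm=tuple(tpm))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise FormatError(
                        f"{path}: line {lineno}: unknown chromosome {chrom}"
                    )
                if cl.end > chrom_lengths[chrom]:
                    raise FormatError(
                        f"{path}: line {lineno}: cluster end {cl.end} beyond "
                        f"chromosome {chrom} (length {chrom_lengths[chrom]})"
                    )
            clusters.append(cl)
    return CAGETagClusterSet(clusters=clusters)


def write_cage_clusters(clusterset: CAGETagClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstrand\tstart\tend\tcounts\ttpm\n")
        for cl in clusterset:
            counts = ",".join(str(c) for c in cl.counts)
            tpm = ",".join(f"{t}:{v:g}" for t, v in cl.tpm)
            fh.write(f"{cl.chrom}\t{cl.strand}\t{cl.start}\t{cl.end}\t"
                     f"{counts}\t{tpm}\n")


# ---------------------------------------------------------------------------
# gene list


def read_gene_list(path: str | Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok and not tok.startswith("#"):
                ids.append(tok)
    return ids


def write_gene_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(gid + "\n")


# ---------------------------------------------------------------------------
# BED export


def write_bed(rows: Iterable[tuple], path_or_handle) -> None:
    """Write an iterable of BED tuples (already-formed columns) as text."""
    if isinstance(path_or_handle, (str, Path)):
        fh = open(path_or_handle, "w")
        close = True
    else:
        fh, close = path_or_handle, False
    try:
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# run configuration

_TSS_MODES = ("all", "most_distal", "highest_tpm", "with_cpg", "without_cpg")
_CODING_MODES = ("coding", "noncoding", "both")
_BACKGROUND_TYPES = ("random", "core", "conserved")


@dataclass
class RunConfig:
    """User-facing analysis parameters.

    ``conservation_threshold`` and ``top_percent_conserved`` are percentages;
    ``random_occurrence`` is the tolerated chance-hit rate in hits per Mbp
    (1 hit per Mbp up to 1 hit per 100 bp, i.e. 1..10000);
    ``max_conserved_tfbs = 0`` means unlimited.
    """

    conservation_threshold: float = 60.0
    top_percent_conserved: float = 100.0
    max_conserved_tfbs: int = 0
    coding_mode: str = "both"
    upstream_len: int = 10000
    downstream_len: int = 5000
    random_occurrence: float = 10.0
    background_type: str = "random"
    tss_mode: str = "all"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 60.0 <= self.conservation_threshold <= 90.0:
            raise ValueError("conservation_threshold must be in [60, 90] %")
        if not 1.0 <= self.top_percent_conserved <= 100.0:
            raise ValueError("top_percent_conserved must be in [1, 100] %")
        if self.max_conserved_tfbs < 0:
            raise ValueError("max_conserved_tfbs must be >= 0 (0 = unlimited)")
        if self.coding_mode not in _CODING_MODES:
            raise ValueError(f"coding_mode must be one of {_CODING_MODES}")
        if not 0 <= self.upstream_len <= 10000:
            raise ValueError("upstream_len must be in [0, 10000] bp")
        if not 0 <= self.downstream_len <= 5000:
            raise ValueError("downstream_len must be in [0, 5000] bp")
        if not 1.0 <= self.random_occurrence <= 10000.0:
            raise ValueError("random_occurrence must be in [1, 10000] hits/Mbp")
        if self.background_type not in _BACKGROUND_TYPES:
            raise ValueError(f"background_type must be one of {_BACKGROUND_TYPES}")
        if self.tss_mode not in _TSS_MODES:
            raise ValueError(f"tss_mode must be one of {_TSS_MODES}")

    def to_text(self) -> str:
        out = []
        for f in fields(self):
            v = getattr(self, f.name)
            out.append(f"{f.name.replace('_', '-')}={v:g}" if isinstance(v, float)
                       else f"{f.name.replace('_', '-')}={v}")
        return "\n".join(out) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(io.StringIO(text), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            name = key.strip().replace("-", "_")
            if name not in casts:
                raise FormatError(f"config line {lineno}: unknown key {key!r}")
            current = cls.__dataclass_fields__[name].default
            if isinstance(current, bool):
                kwargs[name] = val.strip().lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[name] = int(val)
            elif isinstance(current, float):
                kwargs[name] = float(val)
            else:
                kwargs[name] = val.strip()
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())
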