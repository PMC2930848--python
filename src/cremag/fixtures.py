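"""Deterministic synthetic genomes for testing and benchmarking.

The generator emulates every input the engine consumes: a multi-chromosome
genome with genes on both strands, alternative TSSs (1-4 per gene, at least
one gene with 4), two-exon transcripts (giving a realistic coding mask),
CpG-rich island blocks near a subset of TSSs, a conservation track with a
low genome-wide baseline plus elevated stretches inside promoters, and CAGE
tag clusters near most TSSs.  Motif instances can then be planted into
chosen promoters with their footprints marked as highly conserved.

All randomness flows from a single integer seed through per-component
``numpy`` seed sequences (``[seed, component, index]``), so adding genes or
planting motifs never perturbs sequence generated for other components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CAGECluster,
    CAGETagClusterSet,
    ConservationTrack,
    GeneRecord,
    GenomeAnnotation,
    Transcript,
    write_annotation,
    write_cage_clusters,
    write_conservation,
    write_genome,
)
from .promoter_model import reverse_complement
from .pwm_engine import PFM

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_genome",
    "plant_motifs",
    "make_decoy_pwms",
    "cre_like_pfm",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stream-split component tags
_COMP_GENOME = 0
_COMP_GENES = 1
_COMP_ISLANDS = 2
_COMP_CONS = 3
_COMP_CAGE = 4
_COMP_PLANT = 5
_COMP_DECOYS = 6


@dataclass
class FixtureSpec:
    """Parameters of one synthetic genome.

    Lengths in bp; probabilities in [0, 1].  The defaults describe a
    desk-scale genome: 50 genes spaced 30 kb apart on 2 chromosomes, a
    mammalian-like 45 % GC baseline, CpG islands at half the TSSs,
    a low conservation baseline (0.3) with one highly conserved 500-bp
    stretch (0.9) in each proximal promoter, and CAGE clusters at 70 % of
    TSSs.
    """

    seed: int
    n_genes: int = 50
    n_chroms: int = 2
    gene_spacing: int = 30000
    chrom_margin: int = 12000
    max_tss_per_gene: int = 4
    gc_fraction: float = 0.45
    island_prob: float = 0.5
    island_len: int = 800
    island_gc: float = 0.65
    island_cpg_weight: float = 0.22   # fraction of island dinucleotides forced to CG
    cpg_keep_frac: float = 0.20   # CG dinucleotides surviving background depletion
    cons_background: float = 0.30
    cons_noise: float = 0.05
    cons_run_level: float = 0.90
    cons_run_len: int = 500
    cage_prob: float = 0.7
    cage_width: int = 8
    cage_max_tags: int = 50
    tpm_range: tuple[float, float] = (0.5, 60.0)
    tissues: tuple[str, ...] = ("brain", "liver")
    tss_spread: int = 800      # spacing between alternative TSSs of one gene
    tx_len: int = 1400
    exon1_len: int = 200
    exon2_start: int = 1000
    exon2_len: int = 400

    def __post_init__(self):
        for name in ("island_prob", "cage_prob", "gc_fraction", "island_gc",
                     "island_cpg_weight", "cons_background", "cons_run_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1 <= self.max_tss_per_gene <= 4:
            raise ValueError("max_tss_per_gene must be in 1..4")
        if self.gene_spacing < self.tss_spread * 4 + self.tx_len:
            raise ValueError("gene_spacing too small for gene structure: "
                             "genes would overlap")


@dataclass
class FixtureBundle:
    """In-memory fixture: genome + annotation + conservation + CAGE +
    the motif-planting manifest."""

    spec: FixtureSpec
    genome: dict[str, str]
    annotation: GenomeAnnotation
    conservation: ConservationTrack
    cage: CAGETagClusterSet
    manifest: list[dict] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.annotation]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.tsv",
            "conservation": outdir / "conservation.tsv",
            "cage": outdir / "cage_clusters.tsv",
            "manifest": outdir / "planting_manifest.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_annotation(self.annotation, paths["annotation"])
        write_conservation(self.conservation, paths["conservation"])
        write_cage_clusters(self.cage, paths["cage"])
        with open(paths["manifest"], "w") as fh:
            fh.write("#gene\ttss_index\tmatrix\ttss_offset\tstrand\tword\n")
            for row in self.manifest:
                fh.write("{gene}\t{tss_index}\t{matrix}\t{tss_offset}\t"
                         "{strand}\t{word}\n".format(**row))
        return paths


def _rng(seed: int, component: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, component, index])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _deplete_cpg(arr: np.ndarray, rng: np.random.Generator,
                 keep_frac: float) -> np.ndarray:
    """Mutate most CG dinucleotides (C->T, mimicking methyl-C deamination)
    so the background reaches the CpG depletion seen in real genomes."""
    cg = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
    doomed = cg[rng.random(cg.size) >= keep_frac]
    arr[doomed] = ord("T")
    return arr


def _island_block(rng: np.random.Generator, n: int, gc: float,
                  cpg_weight: float) -> np.ndarray:
    """GC-rich block with forced CG dinucleotides (CpG-enriched)."""
    out = _random_bases(rng, n, gc)
    n_pairs = int(cpg_weight * n / 2)
    starts = rng.choice(max(1, n - 1), size=n_pairs, replace=False)
    for s in starts:
        out[s] = ord("C")
        out[s + 1] = ord("G")
    return out


def make_genome(spec: FixtureSpec) -> FixtureBundle:
    """Build the full fixture bundle described by ``spec``.

    Gene ``G0000`` always carries 4 alternative TSSs; other genes draw
    1..max uniformly.  Strands alternate.  Each TSS gets 1-2 two-exon
    transcripts.  CpG island blocks are written just upstream of
    island-bearing TSSs; a conserved stretch is placed inside each gene's
    proximal 1 kb upstream region; CAGE clusters straddle supported TSSs
    with a tag-count peak at the annotated position or up to 2 bp away.
    """
    n_per_chrom = -(-spec.n_genes // spec.n_chroms)  # ceil
    chrom_len = 2 * spec.chrom_margin + n_per_chrom * spec.gene_spacing
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_arrays = {}
    for ci, c in enumerate(chrom_names):
        r = _rng(spec.seed, _COMP_GENOME, ci)
        chrom_arrays[c] = _deplete_cpg(
            _random_bases(r, chrom_len, spec.gc_fraction), r,
            spec.cpg_keep_frac)
    cons_arrays = {}
    for ci, c in enumerate(chrom_names):
        r = _rng(spec.seed, _COMP_CONS, ci)
        arr = spec.cons_background + r.uniform(-spec.cons_noise,
                                               spec.cons_noise, chrom_len)
        cons_arrays[c] = np.clip(arr, 0.0, 1.0)

    genes: list[GeneRecord] = []
    clusters: list[CAGECluster] = []
    for gi in range(spec.n_genes):
        rg = _rng(spec.seed, _COMP_GENES, gi)
        chrom = chrom_names[gi % spec.n_chroms]
        slot = gi // spec.n_chroms
        anchor = spec.chrom_margin + slot * spec.gene_spacing
        strand = "+" if gi % 2 == 0 else "-"
        n_tss = spec.max_tss_per_gene if gi == 0 else \
            int(rg.integers(1, spec.max_tss_per_gene + 1))
        gene_id = f"G{gi:04d}"

        # oriented TSS offsets from the anchor: 0 (most distal) downstream
        tss_offsets = [k * spec.tss_spread for k in range(n_tss)]
        transcripts = []
        for k, off in enumerate(tss_offsets):
            n_tx = int(rg.integers(1, 3))
            for j in range(n_tx):
                # oriented transcript [off, off + tx_len + j*50)
                o_start, o_end = off, off + spec.tx_len + 50 * j
                ex1 = (o_start, o_start + spec.exon1_len)
                ex2 = (off + spec.exon2_start, min(o_end,
                       off + spec.exon2_start + spec.exon2_len))
                if strand == "+":
                    g_start, g_end = anchor + o_start, anchor + o_end
                    exons = tuple(sorted((anchor + a, anchor + b)
                                         for a, b in (ex1, ex2)))
                else:
                    # oriented [a, b) downstream of genomic anchor maps to
                    # genomic [anchor - b + 1, anchor - a + 1)
                    g_start, g_end = anchor - o_end + 1, anchor - o_start + 1
                    exons = tuple(sorted((anchor - b + 1, anchor - a + 1)
                                         for a, b in (ex1, ex2)))
                transcripts.append(Transcript(
                    transcript_id=f"{gene_id}.T{k}{j}",
                    start=g_start, end=g_end, exons=exons))
        genes.append(GeneRecord(gene_id=gene_id, chrom=chrom, strand=strand,
                                transcripts=tuple(transcripts)))

        tss_genomic = [anchor + off if strand == "+" else anchor - off
                       for off in tss_offsets]

        # CpG island block just upstream of island-bearing TSSs
        ri = _rng(spec.seed, _COMP_ISLANDS, gi)
        for k, pos in enumerate(tss_genomic):
            if ri.random() >= spec.island_prob:
                continue
            block = _island_block(ri, spec.island_len, spec.island_gc,
                                  spec.island_cpg_weight)
            # oriented upstream interval [-island_len - 50, -50)
            if strand == "+":
                s = pos - spec.island_len - 50
                chrom_arrays[chrom][s:s + spec.island_len] = block
            else:
                s = pos + 51
                chrom_arrays[chrom][s:s + spec.island_len] = \
                    np.frombuffer(
                        reverse_complement(block.tobytes().decode()).encode(),
                        dtype=np.uint8)

        # conserved stretch inside the proximal upstream kb of every TSS
        rc = _rng(spec.seed, _COMP_CONS, spec.n_chroms + gi)
        for pos in tss_genomic:
            run_off = int(rc.integers(100, 1000 - spec.cons_run_len + 100))
            if strand == "+":
                s = pos - run_off - spec.cons_run_len
            else:
                s = pos + run_off
            s = max(0, min(s, chrom_len - spec.cons_run_len))
            level = spec.cons_run_level + rc.uniform(0, 0.05)
            cons_arrays[chrom][s:s + spec.cons_run_len] = min(level, 1.0)

        # CAGE clusters
        rk = _rng(spec.seed, _COMP_CAGE, gi)
        for pos in tss_genomic:
            if rk.random() >= spec.cage_prob:
                continue
            start = pos - spec.cage_width // 2
            counts = rk.integers(1, spec.cage_max_tags // 2,
                                 size=spec.cage_width)
            peak_shift = int(rk.integers(-2, 3))
            peak = int(np.clip(pos + peak_shift - start, 0, spec.cage_width - 1))
            counts[peak] = spec.cage_max_tags
            tpm = tuple(
                (t, float(np.round(rk.uniform(*spec.tpm_range), 2)))
                for t in spec.tissues
            )
            clusters.append(CAGECluster(
                chrom=chrom, strand=strand, start=start,
                end=start + spec.cage_width,
                counts=tuple(int(c) for c in counts), tpm=tpm))

    genome = {c: a.tobytes().decode("ascii") for c, a in chrom_arrays.items()}
    return FixtureBundle(
        spec=spec,
        genome=genome,
        annotation=GenomeAnnotation(genes=genes),
        conservation=ConservationTrack(cons_arrays),
        cage=CAGETagClusterSet(clusters=clusters),
    )


def plant_motifs(
    bundle: FixtureBundle,
    pfm: PFM,
    gene_ids: list[str],
    sites_per_promoter: int = 2,
    tss_choice: str | int = "distal",
    offsets: list[int] | None = None,
    placement_window: tuple[int, int] = (-900, -60),
    elevate_conservation: float = 0.95,
    sample_from_pfm: bool = False,
    seed: int | None = None,
) -> FixtureBundle:
    """Write motif instances into selected promoters (in place).

    ``tss_choice`` selects which alternative TSS of each gene receives the
    sites: ``"distal"`` (5'-most), ``"proximal"`` (3'-most), ``"all"``, or an
    explicit TSS index.  ``offsets`` fixes TSS-relative oriented positions
    (negative = upstream); otherwise non-overlapping positions are drawn
    from ``placement_window``.  Planted footprints get conservation
    ``elevate_conservation``.  Words are the consensus, or sampled from the
    PFM column frequencies when ``sample_from_pfm``.  Returns the bundle,
    with planted sites appended to its manifest.  Raises when requested
    placements collide.
    """
    if not gene_ids:
        return bundle
    seed = bundle.spec.seed if seed is None else seed
    by_id = bundle.annotation.by_id()
    L = pfm.width
    freqs = pfm.counts / pfm.counts.sum(axis=0)
    occupied: dict[tuple[str, int], bool] = {}

    for pi, gene_id in enumerate(gene_ids):
        gene = by_id[gene_id]
        rp = _rng(seed, _COMP_PLANT, pi)
        tss_positions = gene.tss_positions()  # ascending genomic
        orient = tss_positions if gene.strand == "+" else tss_positions[::-1]
        # orient[0] = most distal (5'-most)
        if tss_choice == "distal":
            chosen = [orient[0]]
        elif tss_choice == "proximal":
            chosen = [orient[-1]]
        elif tss_choice == "all":
            chosen = orient
        else:
            chosen = [orient[int(tss_choice)]]
        chrom_arr = np.frombuffer(
            bundle.genome[gene.chrom].encode(), dtype=np.uint8).copy()
        cons_arr = bundle.conservation[gene.chrom]
        for tss_pos in chosen:
            if offsets is not None:
                site_offs = list(offsets)
                if len(site_offs) < sites_per_promoter:
                    raise ValueError("fewer offsets than sites_per_promoter")
                site_offs = site_offs[:sites_per_promoter]
            else:
                lo, hi = placement_window
                if (hi - lo) < sites_per_promoter * (L + 2):
                    raise ValueError("placement window too small for the "
                                     "requested number of sites")
                site_offs = []
                attempts = 0
                while len(site_offs) < sites_per_promoter:
                    cand = int(rp.integers(lo, hi - L + 1))
                    if all(abs(cand - o) >= L for o in site_offs):
                        site_offs.append(cand)
                    attempts += 1
                    if attempts > 1000:
                        raise RuntimeError("could not place sites without overlap")
            for off in sorted(site_offs):
                if sample_from_pfm:
                    word = "".join("ACGT"[rp.choice(4, p=freqs[:, i])]
                                   for i in range(L))
                else:
                    word = pfm.consensus
                if gene.strand == "+":
                    g_start = tss_pos + off
                    payload = word
                else:
                    g_start = tss_pos - off - L + 1
                    payload = reverse_complement(word)
                g_end = g_start + L
                if g_start < 0 or g_end > len(chrom_arr):
                    raise ValueError(
                        f"{gene_id}: planted site [{g_start},{g_end}) outside "
                        f"chromosome {gene.chrom}")
                for b in range(g_start, g_end):
                    if occupied.get((gene.chrom, b)):
                        raise ValueError(
                            f"{gene_id}: planted site at {gene.chrom}:{g_start} "
                            "collides with an earlier planting")
                for b in range(g_start, g_end):
                    occupied[(gene.chrom, b)] = True
                chrom_arr[g_start:g_end] = np.frombuffer(
                    payload.encode(), dtype=np.uint8)
                cons_arr[g_start:g_end] = elevate_conservation
                ti = orient.index(tss_pos)
                bundle.manifest.append({
                    "gene": gene_id, "tss_index": ti, "matrix": pfm.id,
                    "tss_offset": off, "strand": "+", "word": word,
                })
        bundle.genome[gene.chrom] = chrom_arr.tobytes().decode("ascii")
    return bundle


def make_decoy_pwms(
    n: int,
    widths: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12),
    seed: int = 0,
    column_total: int = 40,
    avoid_consensus: tuple[str, ...] = (),
) -> list[PFM]:
    """Random decoy PFMs with varied information content.

    Column counts are drawn from Dirichlet distributions with concentration
    cycling between sharp (high-IC) and flat (low-IC) columns.  Matrices
    whose consensus appears in ``avoid_consensus`` are redrawn.
    """
    if n < 3:
        raise ValueError("a repertoire needs at least 3 matrices")
    pfms: list[PFM] = []
    for i in range(n):
        r = _rng(seed, _COMP_DECOYS, i)
        width = int(widths[i % len(widths)])
        for _attempt in range(100):
            alpha = 0.3 + 1.7 * ((i % 5) / 4.0)
            cols = []
            for _ in range(width):
                frac = r.dirichlet(np.full(4, alpha))
                counts = np.round(frac * column_total)
                counts[counts.argmax()] += column_total - counts.sum()
                cols.append(np.maximum(counts, 0))
            counts = np.array(cols).T
            pfm = PFM(id=f"DEC{i:04d}.1", name=f"decoy{i}", counts=counts)
            if pfm.consensus not in avoid_consensus:
                pfms.append(pfm)
                break
        else:
            raise RuntimeError("could not draw a decoy avoiding the given "
                               "consensus words")
    return pfms


def cre_like_pfm(sharp: int = 97) -> PFM:
    """A sharp, non-palindromic CRE-like matrix (consensus ``TGACGTGA``).

    Used as the planted 'signal' matrix in recovery experiments; the
    consensus contains the CRE half-site TGACG but is deliberately not the
    palindromic full site, so a planted instance matches on exactly one
    strand at high thresholds.
    """
    consensus = "TGACGTGA"
    counts = np.ones((4, len(consensus)))
    for i, b in enumerate(consensus):
        counts["ACGT".index(b), i] = sharp
    return PFM(id="CRE0001.1", name="CRE-like", counts=counts)
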