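"""Overrepresentation statistics for pooled, filtered promoter hits.

For each matrix, hits from all of a gene's selected alternative promoters
are pooled (duplicate genomic footprints from overlapping windows counted
once), the user's filters are applied, and observed counts are compared with
chance expectations derived from the background frequency table:

* ``tfbs_expected = effective_length / 1e6 * background_rate`` where the
  effective length counts bases surviving the region-level filters (window,
  coding mode, conservation threshold), overlap-deduplicated per gene;
* ``genes_expected = sum_g (1 - exp(-lambda_g))`` under a per-gene Poisson
  model with ``lambda_g = length_g / 1e6 * background_rate``;
* folds are observed/expected; z-scores standardize each fold against the
  fold distribution over ALL matrices in the repertoire (assumed Gaussian),
  and the upper-tail standard-normal probability is the reported p-value;
* the proportion p-value is ``min(1, expected/observed)`` — the fraction of
  observed hits explainable by chance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .background import BackgroundFrequencyTable, optimize_threshold
from .cpg import annotate_tss_with_islands, genome_island_stats
from .io_formats import (
    CAGETagClusterSet,
    ConservationTrack,
    GenomeAnnotation,
    RunConfig,
)
from .promoter_model import (
    PromoterSequence,
    cluster_tss,
    extract_promoter,
    remap_tss_with_cage,
    select_tss,
)
from .pwm_engine import PFM, TFBSHit, pfm_to_pwm, scan

__all__ = [
    "FilterParams",
    "EnrichmentRow",
    "EnrichmentResult",
    "filter_hits",
    "expected_hits",
    "expected_genes",
    "fold_and_z",
    "proportion_p",
    "cpg_comparison",
    "run_enrichment",
]


@dataclass(frozen=True)
class FilterParams:
    """Analysis-side filters; ``conservation_threshold`` is a fraction in
    [0, 1] here (the user-facing config carries a percentage)."""

    conservation_threshold: float = 0.6
    top_percent_conserved: float = 100.0
    max_conserved_tfbs: int = 0          # 0 = unlimited
    coding_mode: str = "both"
    upstream_len: int = 10000
    downstream_len: int = 5000

    @classmethod
    def from_config(cls, config: RunConfig) -> "FilterParams":
        return cls(
            conservation_threshold=config.conservation_threshold / 100.0,
            top_percent_conserved=config.top_percent_conserved,
            max_conserved_tfbs=config.max_conserved_tfbs,
            coding_mode=config.coding_mode,
            upstream_len=config.upstream_len,
            downstream_len=config.downstream_len,
        )


def _region_survivors(prom: PromoterSequence, params: FilterParams) -> np.ndarray:
    """Boolean per-base mask of promoter positions surviving the
    region-level filters (window, coding mode, conservation)."""
    n = len(prom)
    keep = np.zeros(n, dtype=bool)
    lo = max(0, prom.upstream_len - params.upstream_len)
    hi = min(n, prom.upstream_len + params.downstream_len)
    if lo < hi:
        keep[lo:hi] = True
    if params.coding_mode == "coding":
        keep &= prom.coding_mask
    elif params.coding_mode == "noncoding":
        keep &= ~prom.coding_mask
    keep &= prom.conservation >= params.conservation_threshold
    return keep


def _hit_passes_region_filters(
    hit: TFBSHit, prom: PromoterSequence, params: FilterParams
) -> bool:
    lo = prom.upstream_len - params.upstream_len
    hi = prom.upstream_len + params.downstream_len
    if hit.offset < lo or hit.offset + hit.length > hi:
        return False
    if params.coding_mode == "coding" and not hit.coding:
        return False
    if params.coding_mode == "noncoding" and hit.coding:
        return False
    return hit.conservation >= params.conservation_threshold


def filter_hits(
    hits_by_promoter: dict[int, list[TFBSHit]],
    promoters: dict[int, PromoterSequence],
    params: FilterParams,
) -> tuple[list[TFBSHit], int]:
    """Filter and pool one gene's hits for one matrix.

    Filters, in order per promoter: (1) footprint inside the configured
    window; (2) coding mode; (3) conservation at or above the threshold;
    (4) top ``top_percent_conserved`` % of survivors by conservation (count
    = ceiling); (5) at most ``max_conserved_tfbs`` highest-conservation
    hits.  Pooled hits from overlapping promoter windows of the same gene
    are deduplicated by genomic footprint and strand.

    Returns ``(kept hits, effective_length_bp)``; the effective length
    counts genomic bases surviving the region-level filters (1)-(3), each
    base once per gene.
    """
    kept: list[TFBSHit] = []
    genomic_bases: set[int] = set()
    seen_footprints: set[tuple[int, int, str]] = set()
    for tss_index in sorted(promoters):
        prom = promoters[tss_index]
        survivors = [
            h for h in hits_by_promoter.get(tss_index, [])
            if _hit_passes_region_filters(h, prom, params)
        ]
        # rank by conservation (desc), stable on offset then strand
        survivors.sort(key=lambda h: (-h.conservation, h.offset, h.strand))
        if params.top_percent_conserved < 100.0 and survivors:
            n_keep = math.ceil(params.top_percent_conserved / 100.0 * len(survivors))
            survivors = survivors[:n_keep]
        if params.max_conserved_tfbs > 0:
            survivors = survivors[: params.max_conserved_tfbs]
        for h in sorted(survivors, key=lambda h: (h.offset, h.strand)):
            gstart, gend = prom.genomic_span(h.offset, h.length)
            gstrand = h.strand if prom.tss.strand == "+" else (
                "-" if h.strand == "+" else "+")
            footprint = (gstart, gend, gstrand)
            if footprint in seen_footprints:
                continue
            seen_footprints.add(footprint)
            kept.append(h)
        keep_mask = _region_survivors(prom, params)
        offs = np.nonzero(keep_mask)[0]
        if prom.tss.strand == "+":
            genomic_bases.update((prom.window_start + offs).tolist())
        else:
            genomic_bases.update((prom.window_end - 1 - offs).tolist())
    return kept, len(genomic_bases)


def expected_hits(effective_length_bp: float, bg_freq_per_mbp: float) -> float:
    """Chance hit count over the filtered sequence length."""
    if effective_length_bp < 0 or bg_freq_per_mbp < 0:
        raise ValueError("length and background rate must be nonnegative")
    return effective_length_bp / 1e6 * bg_freq_per_mbp


def expected_genes(per_gene_lengths_bp: list[float],
                   bg_freq_per_mbp: float) -> float:
    """Chance number of genes with at least one hit (per-gene Poisson)."""
    lam = np.asarray(per_gene_lengths_bp, dtype=float) / 1e6 * bg_freq_per_mbp
    return float(np.sum(1.0 - np.exp(-lam)))


def fold_and_z(folds: dict[str, float]) -> pd.DataFrame:
    """Standardize observed/expected folds across the matrix repertoire.

    The fold distribution over all matrices is treated as Gaussian; each
    matrix gets ``z = (fold - mean) / sd`` (sample sd, n-1) and the
    upper-tail probability ``p = 1 - Phi(z)``.  A degenerate repertoire
    (all folds equal) yields z = 0, p = 0.5 for every matrix.
    """
    if len(folds) < 3:
        raise ValueError("fold distribution needs at least 3 matrices")
    ids = list(folds)
    values = np.array([folds[m] for m in ids], dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        z = np.zeros_like(values)
        p = np.full_like(values, 0.5)
    else:
        z = (values - mean) / sd
        p = norm.sf(z)
    return pd.DataFrame({"fold": values, "z": z, "p": p}, index=ids)


def proportion_p(observed: int, expected: float) -> float:
    """Fraction of observed hits explainable by chance, capped at 1.

    Zero observed hits give 1 by convention (everything explained)."""
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if observed == 0:
        return 1.0
    return min(1.0, expected / observed)


def cpg_comparison(
    query_island_lengths: list[float],
    genome_mean: float,
    genome_sd: float,
) -> tuple[float, float, float]:
    """One-sided z-test of the query genes' mean CpG-island length against
    the genome-wide per-gene distribution.

    Returns (query mean, genome mean, p).  A zero genome sd makes the test
    undefined; p is reported as 1 with a warning.
    """
    n = len(query_island_lengths)
    if n < 2:
        raise ValueError("CpG comparison requires at least 2 query genes")
    q_mean = float(np.mean(query_island_lengths))
    if genome_sd <= 0.0:
        warnings.warn("genome-wide island-length sd is 0; comparison p-value "
                      "undefined, reporting 1", stacklevel=2)
        return q_mean, genome_mean, 1.0
    z = (q_mean - genome_mean) / (genome_sd / math.sqrt(n))
    return q_mean, genome_mean, float(norm.sf(z))


@dataclass(frozen=True)
class EnrichmentRow:
    matrix_id: str
    tf_name: str
    info_content: float
    genes_with_hits: tuple[str, ...]
    tfbs_number: int
    tfbs_expected: float
    tfbs_fold: float
    tfbs_fold_p: float
    genes_number: int
    genes_expected: float
    genes_fold: float
    genes_fold_p: float
    proportion_p: float


@dataclass
class EnrichmentResult:
    """The five result tables of one run."""

    params: pd.DataFrame            # parameter echo
    per_gene: pd.DataFrame          # gene -> TFBS count after filters
    enrichment: pd.DataFrame        # primary repertoire rows
    enrichment_extra: pd.DataFrame  # second repertoire rows (may be empty)
    cpg: pd.DataFrame               # query vs genome island comparison
    thresholds: dict[str, int]      # optimized per-matrix score thresholds


_ROW_COLUMNS = [
    "matrix_id", "tf_name", "info_content", "genes", "tfbs_number",
    "tfbs_expected", "tfbs_fold", "tfbs_fold_p", "genes_number",
    "genes_expected", "genes_fold", "genes_fold_p", "proportion_p",
    "bonferroni_p",
]


def _sorted_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_ROW_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["tfbs_fold_p", "tfbs_fold", "matrix_id"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def run_enrichment(
    gene_ids: list[str],
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    conservation: ConservationTrack,
    pfms: list[PFM] | dict[str, list[PFM]],
    bg_table: BackgroundFrequencyTable,
    config: RunConfig,
    cage: CAGETagClusterSet | None = None,
    pseudocount: str | float = "sqrt",
    compute_cpg: bool = True,
    island_step: int = 1,
) -> EnrichmentResult:
    """Full overrepresentation analysis of a query gene set.

    ``pfms`` may be one repertoire (list) or ``{repertoire_name: list}``
    with up to two repertoires; fold z-standardization runs over the union
    of all matrices.  All scanning uses per-matrix thresholds optimized
    against ``bg_table`` for ``config.random_occurrence``.
    """
    if isinstance(pfms, dict):
        repertoires = {k: list(v) for k, v in pfms.items()}
    else:
        repertoires = {"primary": list(pfms)}
    all_pfms = [p for reps in repertoires.values() for p in reps]
    if len(all_pfms) < 3:
        raise ValueError("at least 3 matrices are required")

    by_id = annotation.by_id()
    unresolved = [g for g in gene_ids if g not in by_id]
    if unresolved or not gene_ids:
        raise ValueError(
            "query gene ids not found in annotation: "
            + (", ".join(unresolved) if unresolved else "(empty query)")
        )

    params = FilterParams.from_config(config)
    tss_by_gene = cluster_tss(annotation)
    if cage is not None:
        tss_by_gene = {
            g: [remap_tss_with_cage(r, cage) for r in recs]
            for g, recs in tss_by_gene.items()
        }
    need_islands = compute_cpg or config.tss_mode in ("with_cpg", "without_cpg")
    if need_islands:
        tss_by_gene = annotate_tss_with_islands(genome, annotation, tss_by_gene,
                                                step=island_step)
    selected = {g: select_tss(recs, config.tss_mode)
                for g, recs in tss_by_gene.items()}

    # per-matrix optimized thresholds and background rates
    pwms = {p.id: pfm_to_pwm(p, pseudocount) for p in all_pfms}
    thresholds = {
        mid: optimize_threshold(bg_table, mid, config.random_occurrence)
        for mid in pwms
    }
    bg_rate = {mid: bg_table.get(mid, thresholds[mid]) for mid in pwms}

    # promoters for the query genes only
    promoters: dict[str, dict[int, PromoterSequence]] = {}
    for g in gene_ids:
        promoters[g] = {
            r.tss_index: extract_promoter(genome, conservation, annotation, r,
                                          config.upstream_len,
                                          config.downstream_len)
            for r in selected[g]
        }

    # scan + filter, per matrix x gene
    kept_per_matrix: dict[str, dict[str, list[TFBSHit]]] = {}
    eff_len: dict[str, int] = {}
    for g in gene_ids:
        proms = promoters[g]
        first = True
        for mid, pwm in sorted(pwms.items()):
            hits = {ti: scan(pwm, proms[ti], thresholds[mid]) for ti in proms}
            kept, length = filter_hits(hits, proms, params)
            kept_per_matrix.setdefault(mid, {})[g] = kept
            if first:
                eff_len[g] = length  # region-level length is matrix-independent
                first = False
        if first:  # no matrices (unreachable) or no promoters selected
            eff_len[g] = 0

    total_len = float(sum(eff_len.values()))
    per_gene_lens = [float(eff_len[g]) for g in gene_ids]

    obs_hits = {m: sum(len(v) for v in kept_per_matrix[m].values()) for m in pwms}
    genes_hit = {
        m: tuple(sorted(g for g, v in kept_per_matrix[m].items() if v))
        for m in pwms
    }
    exp_hits = {m: expected_hits(total_len, bg_rate[m]) for m in pwms}
    exp_genes = {m: expected_genes(per_gene_lens, bg_rate[m]) for m in pwms}

    def _fold(obs, exp):
        if exp == 0.0:
            return 0.0 if obs == 0 else float("inf")
        return obs / exp

    tfbs_folds = {m: _fold(obs_hits[m], exp_hits[m]) for m in pwms}
    gene_folds = {m: _fold(len(genes_hit[m]), exp_genes[m]) for m in pwms}
    tfbs_stats = fold_and_z(tfbs_folds)
    gene_stats = fold_and_z(gene_folds)

    n_matrices = len(pwms)
    tables = {}
    for rep_name, rep_pfms in repertoires.items():
        rows = []
        for pfm in rep_pfms:
            m = pfm.id
            p_t = float(tfbs_stats.loc[m, "p"])
            rows.append({
                "matrix_id": m,
                "tf_name": pfm.name,
                "info_content": round(pwms[m].info_content, 4),
                "genes": ",".join(genes_hit[m]),
                "tfbs_number": obs_hits[m],
                "tfbs_expected": exp_hits[m],
                "tfbs_fold": tfbs_folds[m],
                "tfbs_fold_p": p_t,
                "genes_number": len(genes_hit[m]),
                "genes_expected": exp_genes[m],
                "genes_fold": gene_folds[m],
                "genes_fold_p": float(gene_stats.loc[m, "p"]),
                "proportion_p": proportion_p(obs_hits[m], exp_hits[m]),
                "bonferroni_p": min(1.0, p_t * n_matrices),
            })
        tables[rep_name] = _sorted_table(rows)

    rep_names = list(repertoires)
    primary_table = tables[rep_names[0]]
    extra_table = tables[rep_names[1]] if len(rep_names) > 1 else \
        pd.DataFrame(columns=_ROW_COLUMNS)

    per_gene_rows = [
        {
            "gene_id": g,
            "n_tss_selected": len(selected[g]),
            "effective_length_bp": eff_len[g],
            "tfbs_count": sum(len(kept_per_matrix[m][g]) for m in pwms),
        }
        for g in gene_ids
    ]
    per_gene_df = pd.DataFrame(per_gene_rows)

    if need_islands and len(annotation) >= 2:
        genome_per_gene = {
            g: sum(r.cpg_island_total_len for r in select_tss(recs, config.tss_mode))
            for g, recs in tss_by_gene.items()
        }
        g_mean, g_sd = genome_island_stats(genome_per_gene)
        query_lengths = [float(genome_per_gene[g]) for g in gene_ids]
        q_mean, g_mean, p = cpg_comparison(query_lengths, g_mean, g_sd)
        cpg_df = pd.DataFrame([{
            "query_mean_island_len": q_mean,
            "genome_mean_island_len": g_mean,
            "genome_sd_island_len": g_sd,
            "p_value": p,
        }])
    else:
        cpg_df = pd.DataFrame(columns=[
            "query_mean_island_len", "genome_mean_island_len",
            "genome_sd_island_len", "p_value"])

    params_df = pd.DataFrame(
        [{"parameter": k.replace("_", "-"), "value": v}
         for k, v in vars(config).items()]
    )
    return EnrichmentResult(
        params=params_df,
        per_gene=per_gene_df,
        enrichment=primary_table,
        enrichment_extra=extra_table,
        cpg=cpg_df,
        thresholds=thresholds,
    )
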