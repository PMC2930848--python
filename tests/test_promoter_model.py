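import numpy as np
import pytest

from cremag.io_formats import (
    CAGECluster,
    CAGETagClusterSet,
    ConservationTrack,
    GeneRecord,
    GenomeAnnotation,
    Transcript,
)
from cremag.promoter_model import (
    NO_CAGE_TPM,
    TSSRecord,
    cluster_tss,
    extract_promoter,
    remap_tss_with_cage,
    reverse_complement,
    select_tss,
)


def _gene(gene_id="G1", chrom="chr1", strand="+", starts=(100,), length=500):
    txs = []
    for i, s in enumerate(starts):
        if strand == "+":
            txs.append(Transcript(f"{gene_id}.T{i}", s, s + length,
                                  ((s, s + 50),)))
        else:
            txs.append(Transcript(f"{gene_id}.T{i}", s - length + 1, s + 1,
                                  ((s - 49, s + 1),)))
    return GeneRecord(gene_id=gene_id, chrom=chrom, strand=strand,
                      transcripts=tuple(txs))


def _tss(position, strand="+", **kw):
    return TSSRecord(gene_id="G1", chrom="chr1", strand=strand,
                     position=position, **kw)


class TestClusterTss:
    def test_duplicate_starts_collapse(self):
        ann = GenomeAnnotation([_gene(starts=(100, 100, 250))])
        recs = cluster_tss(ann)["G1"]
        assert [r.position for r in recs] == [100, 250]
        assert recs[0].transcript_ids == ("G1.T0", "G1.T1")

    def test_single_transcript(self):
        recs = cluster_tss(GenomeAnnotation([_gene(starts=(100,))]))["G1"]
        assert len(recs) == 1 and recs[0].position == 100

    def test_four_distinct_starts(self):
        ann = GenomeAnnotation([_gene(starts=(100, 900, 1700, 2500))])
        recs = cluster_tss(ann)["G1"]
        assert len(recs) == 4
        # indexed 5' -> 3': index 0 is the most distal start
        assert recs[0].position == 100 and recs[3].position == 2500

    def test_minus_strand_ordering(self):
        ann = GenomeAnnotation([_gene(strand="-", starts=(3000, 2200, 1400))])
        recs = cluster_tss(ann)["G1"]
        assert [r.position for r in recs] == [3000, 2200, 1400]


class TestCageRemap:
    def _clusters(self, *cl):
        return CAGETagClusterSet(list(cl))

    def test_peak_position_and_tpm(self):
        cl = CAGECluster("chr1", "+", 1005, 1012,
                         counts=(12, 0, 0, 0, 0, 30, 0),
                         tpm=(("liver", 4.2), ("brain", 7.5)))
        out = remap_tss_with_cage(_tss(1000), self._clusters(cl))
        assert out.position == 1010
        assert out.tpm == 7.5

    def test_no_cluster_in_range_keeps_position_with_sentinel(self):
        cl = CAGECluster("chr1", "+", 1500, 1504, counts=(5, 5, 5, 5),
                         tpm=(("liver", 2.0),))
        out = remap_tss_with_cage(_tss(1000), self._clusters(cl))
        assert out.position == 1000 and out.tpm == NO_CAGE_TPM

    def test_closest_cluster_wins(self):
        near = CAGECluster("chr1", "+", 1050, 1054, counts=(1, 9, 1, 1),
                           tpm=(("liver", 1.0),))
        far = CAGECluster("chr1", "+", 1120, 1124, counts=(50, 1, 1, 1),
                          tpm=(("liver", 9.0),))
        out = remap_tss_with_cage(_tss(1000), self._clusters(near, far))
        assert out.position == 1051 and out.tpm == 1.0

    def test_strand_restriction(self):
        cl = CAGECluster("chr1", "-", 1002, 1006, counts=(9, 1, 1, 1),
                         tpm=(("liver", 2.0),))
        out = remap_tss_with_cage(_tss(1000), self._clusters(cl))
        assert out.tpm == NO_CAGE_TPM

    def test_displacement_bounded(self):
        # remap can never move a TSS farther than range + cluster width
        cl = CAGECluster("chr1", "+", 1195, 1235, counts=tuple([1] * 39 + [9]),
                         tpm=(("liver", 2.0),))
        out = remap_tss_with_cage(_tss(1000), self._clusters(cl))
        assert abs(out.position - 1000) <= 200 + 40


class TestExtractPromoter:
    @pytest.fixture
    def genome(self):
        rng = np.random.default_rng(5)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=20000))}

    @pytest.fixture
    def empty_ann(self):
        return GenomeAnnotation([])

    def test_plus_strand_window(self, genome, empty_ann):
        prom = extract_promoter(genome, None, empty_ann, _tss(10000), 10, 5)
        assert prom.seq == genome["chr1"][9990:10005]
        assert prom.window_start == 9990 and prom.window_end == 10005

    def test_minus_strand_window_is_reverse_complement(self, genome, empty_ann):
        prom = extract_promoter(genome, None, empty_ann,
                                _tss(10000, strand="-"), 10, 5)
        assert prom.seq == reverse_complement(genome["chr1"][9996:10011])

    def test_tss_base_sits_at_upstream_index(self, genome, empty_ann):
        for strand in "+-":
            prom = extract_promoter(genome, None, empty_ann,
                                    _tss(10000, strand=strand), 10, 5)
            base = genome["chr1"][10000]
            expected = base if strand == "+" else reverse_complement(base)
            assert prom.seq[prom.upstream_len] == expected

    def test_truncation_at_chromosome_start(self, genome, empty_ann):
        prom = extract_promoter(genome, None, empty_ann, _tss(3), 10, 5)
        assert len(prom) == 3 + 5
        assert prom.upstream_len == 3 and prom.truncated_upstream == 7

    def test_conservation_orientation(self, empty_ann):
        genome = {"chr1": "A" * 100}
        scores = np.zeros(100)
        scores[60] = 0.9  # one marked base downstream of a minus-strand TSS
        track = ConservationTrack({"chr1": scores})
        prom = extract_promoter(genome, track, empty_ann,
                                _tss(70, strand="-"), 10, 20)
        # genomic 60 is 10 bases downstream of the TSS on '-'
        assert prom.conservation[prom.upstream_len + 10] == pytest.approx(0.9)

    def test_coding_mask_marks_exons(self, genome):
        ann = GenomeAnnotation([_gene(starts=(10000,))])
        prom = extract_promoter(genome, None, ann, _tss(10000), 100, 100)
        # exon (10000, 10050) of the gene overlaps the downstream half
        assert prom.coding_mask[100:150].all()
        assert not prom.coding_mask[:100].any()

    def test_unknown_chromosome_rejected(self, genome, empty_ann):
        bad = TSSRecord(gene_id="G1", chrom="chrZ", strand="+", position=5)
        with pytest.raises(KeyError):
            extract_promoter(genome, None, empty_ann, bad, 10, 5)


class TestSelectTss:
    def _records(self, positions, strand="+", tpms=None, islands=None):
        recs = []
        for i, p in enumerate(positions):
            recs.append(TSSRecord(
                gene_id="G1", chrom="chr1", strand=strand, position=p,
                tss_index=i,
                tpm=NO_CAGE_TPM if tpms is None else tpms[i],
                cpg_island_total_len=0 if islands is None else islands[i]))
        return recs

    def test_all_is_identity(self):
        recs = self._records([100, 250, 400])
        assert select_tss(recs, "all") == recs

    def test_most_distal_plus(self):
        recs = self._records([100, 250, 400])
        assert select_tss(recs, "most_distal")[0].position == 100

    def test_most_distal_minus(self):
        recs = self._records([100, 250, 400], strand="-")
        assert select_tss(recs, "most_distal")[0].position == 400

    def test_highest_tpm(self):
        recs = self._records([100, 250, 400], tpms=[-1.0, 3.0, 7.5])
        assert select_tss(recs, "highest_tpm")[0].tpm == 7.5

    def test_highest_tpm_all_sentinel_falls_back_with_warning(self):
        recs = self._records([100, 250, 400])
        with pytest.warns(UserWarning, match="most distal"):
            out = select_tss(recs, "highest_tpm")
        assert out[0].position == 100

    def test_cpg_modes_partition(self):
        recs = self._records([100, 250, 400], islands=[0, 0, 512])
        with_cpg = select_tss(recs, "with_cpg")
        without = select_tss(recs, "without_cpg")
        assert len(with_cpg) == 1 and with_cpg[0].cpg_island_total_len == 512
        assert sorted(r.position for r in with_cpg + without) == [100, 250, 400]

    def test_mixed_gene_rejected(self):
        recs = self._records([100])
        other = TSSRecord(gene_id="G2", chrom="chr1", strand="+", position=5)
        with pytest.raises(ValueError):
            select_tss(recs + [other], "all")
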