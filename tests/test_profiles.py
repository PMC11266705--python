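"""TSS metaplots, gene-body binning, asymmetry, heatmap ordering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cpdseq import (
    DataError,
    GeneRecord,
    GeneSet,
    Genome,
    LesionMap,
    SignalTrack,
    asymmetry_score,
    binned_repair,
    classify_strand,
    gene_bins,
    heatmap_matrix,
    nucleosome_overlay,
    tss_profile,
)
from cpdseq.normalize import NormalizationFactor
from cpdseq.profiles import read_cdt, write_cdt
from cpdseq.simulate import mirror_genes, mirror_lesions

UNIT = NormalizationFactor(1.0, 1.0, 1, 1)


def _uniform_map(lengths, value):
    lmap = LesionMap(lengths)
    for c in lengths:
        for s in "+-":
            lmap.counts[c][s][:] = value
    return lmap


class TestClassifyStrand:
    def test_definition(self):
        assert classify_strand("+", "+") == "NTS"
        assert classify_strand("-", "+") == "TS"

    def test_flipping_gene_strand_swaps_every_class(self):
        for ls in "+-":
            assert classify_strand(ls, "+") != classify_strand(ls, "-")


class TestTssProfile:
    def test_uniform_counts_give_flat_unit_profile(self):
        lengths = {"chr1": 3000}
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1000, 2000, 1.0)])
        prof = tss_profile(
            _uniform_map(lengths, 3), _uniform_map(lengths, 3), genes, UNIT,
            window=(-200, 640),
        )
        assert np.allclose(prof.table["fraction"], 1.0)
        # smoothing never touches the raw fraction column
        assert np.allclose(prof.table["fraction_smoothed"].dropna(), 1.0)

    def test_single_gene_template_strand_lesion(self):
        lengths = {"chr1": 3000}
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1000, 2000, 1.0)])
        m0, mt = LesionMap(lengths), LesionMap(lengths)
        m0.counts["chr1"]["-"][1010] = 4  # template strand of a plus gene
        mt.counts["chr1"]["-"][1010] = 1
        prof = tss_profile(m0, mt, genes, UNIT, smooth_width=None)
        ts = prof.fractions("TS")
        nts = prof.fractions("NTS")
        assert ts[10] == pytest.approx(0.25)
        assert math.isnan(nts[10])

    def test_mirror_gene_reproduces_profile(self, rng):
        n = 4000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        genome = Genome({"chr1": seq})
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1200, 2400, 1.0)])
        m0, mt = LesionMap(genome.lengths), LesionMap(genome.lengths)
        for s in "+-":
            pos = rng.choice(n, size=200)
            m0.counts["chr1"][s] += np.bincount(pos, minlength=n)
            pos = rng.choice(n, size=120)
            mt.counts["chr1"][s] += np.bincount(pos, minlength=n)
        fwd = tss_profile(m0, mt, genes, UNIT, smooth_width=None)
        rev = tss_profile(
            mirror_lesions(m0), mirror_lesions(mt),
            mirror_genes(genes, genome.lengths), UNIT, smooth_width=None,
        )
        pd.testing.assert_frame_equal(fwd.table, rev.table)

    def test_empty_gene_set_is_an_error(self):
        lengths = {"chr1": 1000}
        with pytest.raises(DataError):
            tss_profile(_uniform_map(lengths, 1), _uniform_map(lengths, 1), GeneSet(), UNIT)


class TestNucleosomeOverlay:
    def test_constant_track_gives_flat_overlay(self):
        track = SignalTrack({"chr1": np.full(3000, 2.5)})
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1000, 2000, 1.0)])
        overlay = nucleosome_overlay(track, genes, (-200, 640))
        assert np.allclose(overlay, 2.5)

    def test_impulse_lands_at_its_offset(self):
        track = SignalTrack({"chr1": np.zeros(3000)})
        track["chr1"][1060] = 1.0
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1000, 2000, 1.0)])
        overlay = nucleosome_overlay(track, genes, (-200, 640))
        offsets = np.arange(-200, 640)
        assert offsets[int(np.argmax(overlay))] == 60

    def test_mean_not_sum_over_genes(self):
        track = SignalTrack({"chr1": np.full(6000, 4.0)})
        genes = GeneSet(
            [
                GeneRecord("g1", "chr1", "+", 1000, 2000, 1.0),
                GeneRecord("g2", "chr1", "+", 3000, 4000, 1.0),
            ]
        )
        overlay = nucleosome_overlay(track, genes, (-100, 100))
        assert np.allclose(overlay, 4.0)


def _per_base_bin(o: int, length: int, n_body: int = 6) -> int:
    return n_body * o // length


class TestGeneBins:
    def test_minimal_gene_six_single_base_bins(self):
        g = GeneRecord("g", "chr1", "+", 100, 106, 1.0)
        body = [b for b in gene_bins(g) if b.kind == "body"]
        assert [b.size for b in body] == [1] * 6
        assert body[0].start == 100 and body[-1].end == 106

    def test_length_100_sizes(self):
        g = GeneRecord("g", "chr1", "+", 1000, 1100, 1.0)
        body = [b for b in gene_bins(g) if b.kind == "body"]
        assert [b.size for b in body] == [17, 17, 16, 17, 17, 16]

    def test_minus_gene_bin_zero_abuts_tss(self):
        g = GeneRecord("g", "chr1", "-", 699, 99, 1.0)
        bins = gene_bins(g)
        body = [b for b in bins if b.kind == "body"]
        # first body bin holds the highest genomic coordinates, ending at the TSS
        assert body[0].end == 700
        assert body[-1].start == 100
        # per-base orientation oracle
        length = 600
        for o in range(length):
            pos = g.tss - o
            k = _per_base_bin(o, length)
            assert body[k].start <= pos < body[k].end

    def test_flanks_exactly_167bp_and_adjacent(self):
        g = GeneRecord("g", "chr1", "+", 2000, 2600, 1.0)
        bins = gene_bins(g)
        up = [b for b in bins if b.kind == "upstream"]
        down = [b for b in bins if b.kind == "downstream"]
        assert all(b.size == 167 for b in up + down)
        assert up[-1].end == 2000 and up[0].start == 2000 - 3 * 167
        assert down[0].start == 2600 and down[-1].end == 2600 + 3 * 167

    def test_too_short_gene_rejected(self):
        g = GeneRecord("g", "chr1", "+", 10, 15, 1.0)
        with pytest.raises(DataError, match="< 6"):
            gene_bins(g)

    @given(
        length=st.integers(min_value=6, max_value=5000),
        strand=st.sampled_from(["+", "-"]),
    )
    def test_intervals_agree_with_per_base_rule(self, length, strand):
        tss = 6000 if strand == "-" else 1000
        tes = tss + length if strand == "+" else tss - length
        g = GeneRecord("g", "chr1", strand, tss, tes, 1.0)
        body = [b for b in gene_bins(g) if b.kind == "body"]
        sizes = [b.size for b in body]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == length  # exact cover of the transcribed span
        for o in range(length):
            pos = tss + o if strand == "+" else tss - o
            k = _per_base_bin(o, length)
            assert body[k].start <= pos < body[k].end


def _two_gene_fixture(rng):
    lengths = {"chr1": 6000}
    genes = GeneSet(
        [
            GeneRecord("g1", "chr1", "+", 800, 1700, 2.0),
            GeneRecord("g2", "chr1", "-", 4599, 3599, 5.0),
        ]
    )
    m0, mt = LesionMap(lengths), LesionMap(lengths)
    for s in "+-":
        m0.counts["chr1"][s] += np.bincount(rng.choice(6000, size=3000), minlength=6000)
        mt.counts["chr1"][s] += np.bincount(rng.choice(6000, size=1500), minlength=6000)
    return lengths, genes, m0, mt


class TestBinnedRepair:
    def test_uniform_no_repair_gives_unit_fractions(self):
        lengths = {"chr1": 4000}
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1500, 2100, 1.0)])
        b = binned_repair(_uniform_map(lengths, 2), _uniform_map(lengths, 2), genes, UNIT)
        assert np.allclose(b.aggregate["fraction"], 1.0)
        assert len(b.aggregate) == 12 * 2

    def test_counts_match_independent_per_base_tally(self, rng):
        lengths, genes, m0, mt = _two_gene_fixture(rng)
        b = binned_repair(m0, mt, genes, UNIT)
        # independent oracle: assign every base to its bin by the floor rule
        expect: dict[tuple[str, int, str], int] = {}
        for g in genes:
            length = g.length
            for o in range(length):
                pos = g.tss + o if g.strand == "+" else g.tss - o
                k = 6 * o // length
                for ls in "+-":
                    sc = "NTS" if ls == g.strand else "TS"
                    key = (g.id, 3 + k, sc)
                    expect[key] = expect.get(key, 0) + int(m0.counts["chr1"][ls][pos])
        body = b.per_gene[b.per_gene["kind"] == "body"]
        for row in body.itertuples(index=False):
            assert row.counts_0 == expect.get((row.gene, row.bin, row.strand_class), 0)

    def test_aggregate_equals_sum_of_per_gene(self, rng):
        lengths, genes, m0, mt = _two_gene_fixture(rng)
        b = binned_repair(m0, mt, genes, UNIT)
        resum = (
            b.per_gene.groupby(["bin", "strand_class"])[["counts_0", "counts_t"]]
            .sum()
            .reset_index()
        )
        merged = b.aggregate.merge(resum, on=["bin", "strand_class"], suffixes=("", "_r"))
        assert (merged["counts_0"] == merged["counts_0_r"]).all()
        assert (merged["counts_t"] == merged["counts_t_r"]).all()

    def test_genes_without_tes_are_excluded(self, rng):
        lengths, genes, m0, mt = _two_gene_fixture(rng)
        genes = GeneSet(genes.genes + [GeneRecord("g3", "chr1", "+", 5000, None, 1.0)])
        b = binned_repair(m0, mt, genes, UNIT)
        assert b.n_genes == 2 and b.n_excluded == 1


class TestAsymmetry:
    def test_symmetric_repair_gives_zero(self):
        lengths = {"chr1": 4000}
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1500, 2100, 1.0)])
        b = binned_repair(_uniform_map(lengths, 4), _uniform_map(lengths, 2), genes, UNIT)
        res = asymmetry_score(b)
        assert np.allclose(res.per_bin["log2_ratio"], 0.0)
        assert res.average == 0.0

    def test_halved_template_strand_gives_minus_one(self):
        lengths = {"chr1": 4000}
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1500, 2100, 1.0)])
        m0 = _uniform_map(lengths, 4)
        mt = LesionMap(lengths)
        mt.counts["chr1"]["-"][:] = 2  # TS of a plus gene
        mt.counts["chr1"]["+"][:] = 4
        res = asymmetry_score(binned_repair(m0, mt, genes, UNIT))
        body = res.per_bin[res.per_bin["kind"] == "body"]
        assert np.allclose(body["log2_ratio"], -1.0)
        assert res.average == pytest.approx(-1.0)

    def test_undefined_body_bin_propagates_unless_allowed(self):
        lengths = {"chr1": 4000}
        genes = GeneSet([GeneRecord("g1", "chr1", "+", 1500, 2100, 1.0)])
        m0 = _uniform_map(lengths, 4)
        m0.counts["chr1"]["-"][1500:1600] = 0  # zero 0h counts in bin 0 on TS
        mt = _uniform_map(lengths, 2)
        mt.counts["chr1"]["-"][1500:1600] = 0
        b = binned_repair(m0, mt, genes, UNIT)
        assert math.isnan(asymmetry_score(b).average)
        res = asymmetry_score(b, allow_undefined=True)
        assert res.n_body_defined == 5 and res.average == pytest.approx(0.0)


class TestHeatmap:
    def _binned(self, rng, txn):
        lengths = {"chr1": 9000}
        genes = GeneSet(
            [
                GeneRecord(f"gene{i + 1}", "chr1", "+", 1000 + 2000 * i, 1600 + 2000 * i, tf)
                for i, tf in enumerate(txn)
            ]
        )
        m0 = _uniform_map(lengths, 3)
        mt = _uniform_map(lengths, 1)
        return binned_repair(m0, mt, genes, UNIT)

    def test_rows_ordered_by_descending_txn_freq(self, rng):
        mats = heatmap_matrix(self._binned(rng, [5.0, 1.0, 9.0]))
        assert list(mats["TS"].index) == ["gene3", "gene1", "gene2"]

    def test_ties_broken_lexicographically_and_missing_sink(self, rng):
        mats = heatmap_matrix(self._binned(rng, [2.0, 2.0, None]))
        assert list(mats["TS"].index) == ["gene1", "gene2", "gene3"]

    def test_cdt_round_trip(self, rng, tmp_path):
        mats = heatmap_matrix(self._binned(rng, [5.0, 1.0, 9.0]))
        path = tmp_path / "m.cdt"
        write_cdt(mats["NTS"], path)
        back = read_cdt(path)
        pd.testing.assert_frame_equal(back, mats["NTS"], check_names=False)
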