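"""Block partition arithmetic, quantification oracles, scoring and ranking."""

import numpy as np
import pytest

from cardioquant import polii
from cardioquant.polii import (
    BlockProfile,
    assign_peaks_to_genes,
    block_partition,
    block_quantify,
    enrichment_score,
    metagene_average,
    normalize_track,
    rank_and_filter,
)
from cardioquant.track_io import BinnedTrack, GeneModel, GenomicInterval, PeakCall


def make_gene(start, end, strand="+", name="g", chrom="chr1"):
    return GeneModel(GenomicInterval(chrom, start, end, strand), name)


def uniform_track(chrom_bins, bin_width=10, density=1.0):
    """Normalized track with constant density everywhere."""
    return BinnedTrack(
        bin_width=bin_width,
        values={c: np.full(n, density) for c, n in chrom_bins.items()},
        normalized=True,
    )


def per_bp_oracle(track, blocks):
    """Brute force: expand bins to per-bp density and average per block."""
    out = []
    for blk in blocks:
        if blk.interval is None:
            out.append(0.0)
            continue
        total = 0.0
        arr = track.values[blk.interval.chrom]
        for bp in range(blk.interval.start, blk.interval.end):
            idx = bp // track.bin_width
            if idx < arr.size:
                v = arr[idx]
                total += v if track.normalized else v / track.bin_width
        out.append(total / blk.width)
    return np.array(out)


class TestNormalize:
    def test_unit_definition(self):
        # 10 reads in a 10 bp bin at 1M mapped reads -> density 1.0 /bp /M
        t = BinnedTrack(bin_width=10, values={"c": np.array([10.0, 0.0])})
        n = normalize_track(t, 1_000_000)
        np.testing.assert_allclose(n.bin_values("c"), [1.0, 0.0])
        assert n.normalized and not t.normalized

    def test_inverse_round_trip(self, rng):
        vals = rng.poisson(5, 100).astype(float)
        t = BinnedTrack(bin_width=10, values={"c": vals})
        n = normalize_track(t, 3_456_789)
        back = n.bin_values("c") * 10 * (3_456_789 / 1e6)
        np.testing.assert_allclose(back, vals, rtol=1e-12)

    def test_double_normalization_rejected(self):
        t = BinnedTrack(values={"c": np.ones(3)})
        with pytest.raises(ValueError, match="already"):
            normalize_track(normalize_track(t, 100), 100)

    def test_missing_depth_rejected(self):
        t = BinnedTrack(values={"c": np.ones(3)})
        with pytest.raises(ValueError, match="total_mapped_reads"):
            normalize_track(t)


class TestBlockPartition:
    def test_plus_strand_defaults(self):
        part = block_partition(make_gene(1000, 2000, "+"))
        ivs = [b.interval for b in part.blocks]
        # 5 upstream blocks tile [500, 1000), most-upstream first
        assert (ivs[0].start, ivs[0].end) == (500, 600)
        assert (ivs[4].start, ivs[4].end) == (900, 1000)
        # 10 body blocks of 100 bp tile [1000, 2000)
        for i in range(10):
            assert (ivs[5 + i].start, ivs[5 + i].end) == (1000 + 100 * i, 1100 + 100 * i)
        # 10 downstream blocks tile [2000, 3000)
        assert (ivs[15].start, ivs[15].end) == (2000, 2100)
        assert (ivs[24].start, ivs[24].end) == (2900, 3000)

    def test_minus_strand_reverses_genomic_order(self):
        part = block_partition(make_gene(1000, 2000, "-"))
        ivs = [b.interval for b in part.blocks]
        # index 0 = most upstream in transcription direction = highest coords
        assert (ivs[0].start, ivs[0].end) == (2400, 2500)
        assert (ivs[5].start, ivs[5].end) == (1900, 2000)  # first body block
        assert (ivs[14].start, ivs[14].end) == (1000, 1100)
        # 10 downstream blocks tile [0, 1000), nearest TES first
        assert (ivs[15].start, ivs[15].end) == (900, 1000)
        assert (ivs[24].start, ivs[24].end) == (0, 100)

    @pytest.mark.parametrize("length", list(range(10, 1001)))
    def test_body_boundary_arithmetic_exhaustive(self, length):
        part = block_partition(make_gene(5000, 5000 + length, "+"))
        widths = [b.width for b in part.body_blocks]
        assert sum(widths) == length
        assert max(widths) - min(widths) <= 1
        # contiguous, non-overlapping tiling
        body = part.body_blocks
        for a, b in zip(body, body[1:]):
            assert a.interval.end == b.interval.start

    def test_gene_1003bp_mixed_widths(self):
        part = block_partition(make_gene(0, 1003, "+"))
        widths = [b.width for b in part.body_blocks]
        assert sorted(set(widths)) == [100, 101] and sum(widths) == 1003

    def test_flank_clipped_at_zero_and_flagged(self):
        part = block_partition(make_gene(100, 1100, "+"))
        # upstream span [-400, 100): four blocks fall entirely below zero
        assert all(part.blocks[i].interval is None for i in range(4))
        assert (part.blocks[4].interval.start, part.blocks[4].interval.end) == (0, 100)
        assert part.any_clipped

    def test_body_past_chrom_end_rejected(self):
        with pytest.raises(ValueError, match="past declared chromosome"):
            block_partition(make_gene(0, 1000, "+"), chrom_length=900)


class TestBlockQuantify:
    def test_uniform_density_all_blocks_equal(self):
        t = uniform_track({"chr1": 500}, density=2.5)
        part = block_partition(make_gene(1000, 2000, "+"))
        prof = block_quantify(t, part)
        np.testing.assert_allclose(prof.values, 2.5)

    def test_pro_rata_half_block(self):
        # density 2.0 over exactly the first half of the first body block
        vals = np.zeros(400)
        vals[100:105] = 2.0  # bp 1000..1050 at bin width 10
        t = BinnedTrack(bin_width=10, values={"chr1": vals}, normalized=True)
        prof = block_quantify(t, block_partition(make_gene(1000, 2000, "+")))
        assert prof.values[5] == pytest.approx(1.0)
        assert prof.values[6:].sum() == 0

    def test_requires_normalized_track(self):
        t = BinnedTrack(values={"chr1": np.ones(400)})
        with pytest.raises(ValueError, match="normalized"):
            block_quantify(t, block_partition(make_gene(1000, 2000, "+")))

    def test_missing_chromosome_names_gene(self):
        t = uniform_track({"chr9": 10})
        with pytest.raises(KeyError, match="chr1"):
            block_quantify(t, block_partition(make_gene(1000, 2000, "+", "geneZ")))
        with pytest.raises(KeyError, match="geneZ"):
            block_quantify(t, block_partition(make_gene(1000, 2000, "+", "geneZ")))

    def test_matches_per_base_oracle_random(self, rng):
        """200 random genes on random tracks agree with bp-level brute force."""
        for _ in range(200):
            bw = int(rng.integers(1, 20))
            nbins = int(rng.integers(50, 300))
            t = BinnedTrack(
                bin_width=bw,
                values={"chr1": rng.random(nbins) * 5},
                normalized=True,
            )
            L = int(rng.integers(10, 400))
            start = int(rng.integers(0, max(nbins * bw - L, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = make_gene(start, start + L, strand)
            part = block_partition(gene)
            prof = block_quantify(t, part)
            np.testing.assert_allclose(
                prof.values, per_bp_oracle(t, part.blocks), rtol=1e-9, atol=1e-12
            )

    def test_conservation_body_integral(self, rng):
        """Sum over body blocks of value*width equals the per-bp body integral."""
        t = BinnedTrack(bin_width=7, values={"chr1": rng.random(300) * 3},
                        normalized=True)
        gene = make_gene(123, 1456, "+")
        part = block_partition(gene)
        prof = block_quantify(t, part)
        widths = np.array([b.width for b in part.body_blocks])
        lhs = float((prof.body_values * widths).sum())
        rhs = t.interval_integral("chr1", 123, 1456)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_strand_symmetry_mirrored_coverage(self, rng):
        """Reflected gene over mirrored coverage gives the reversed profile."""
        bw = 1  # mirror exactly at bp resolution
        n = 5000
        vals = rng.random(n)
        t_fwd = BinnedTrack(bin_width=bw, values={"chr1": vals}, normalized=True)
        t_rev = BinnedTrack(bin_width=bw, values={"chr1": vals[::-1].copy()},
                            normalized=True)
        start, end = 1700, 2733
        g_plus = make_gene(start, end, "+")
        g_minus = make_gene(n - end, n - start, "-")
        p_plus = block_quantify(t_fwd, block_partition(g_plus))
        p_minus = block_quantify(t_rev, block_partition(g_minus))
        np.testing.assert_allclose(p_plus.values, p_minus.values, rtol=1e-12)

    def test_depth_doubling_halves_values(self, rng):
        raw = BinnedTrack(bin_width=10,
                          values={"chr1": rng.poisson(4, 400).astype(float)})
        g = make_gene(1000, 2000, "+")
        p1 = block_quantify(normalize_track(raw, 1_000_000), block_partition(g))
        p2 = block_quantify(normalize_track(raw, 2_000_000), block_partition(g))
        np.testing.assert_allclose(p2.values, p1.values / 2, rtol=1e-12)


class TestScore:
    def test_all_zero(self):
        prof = BlockProfile("g", np.zeros(25), 100)
        assert enrichment_score(prof) == 0.0

    @pytest.mark.parametrize("d", [0.5, 1.0, 3.7])
    def test_uniform_closed_form_10d(self, d):
        for L in (10, 137, 1003, 10_000):
            t = uniform_track({"chr1": (3 * L) // 10 + 200}, bin_width=10, density=d)
            prof = block_quantify(t, block_partition(make_gene(L, 2 * L, "+")))
            assert enrichment_score(prof) == pytest.approx(10 * d, rel=1e-9)

    def test_random_profile_resummation(self, rng):
        vals = rng.random(25)
        prof = BlockProfile("g", vals, 50)
        assert enrichment_score(prof) == pytest.approx(sum(vals[5:15]), rel=1e-12)


class TestMetagene:
    def test_mean_is_idempotent_on_copies(self, rng):
        p = BlockProfile("g", rng.random(25), 10)
        mg = metagene_average([p] * 7, "copies")
        np.testing.assert_allclose(mg.values, p.values)
        assert mg.n_genes == 7

    def test_zero_and_two_average_to_one(self):
        a = BlockProfile("a", np.zeros(25), 10)
        b = BlockProfile("b", np.full(25, 2.0), 10)
        np.testing.assert_allclose(metagene_average([a, b]).values, 1.0)

    def test_matches_naive_column_means(self, rng):
        profs = [BlockProfile(f"g{i}", rng.random(25), 10) for i in range(100)]
        mg = metagene_average(profs)
        naive = np.array([[p.values[j] for p in profs] for j in range(25)]).mean(axis=1)
        np.testing.assert_allclose(mg.values, naive, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metagene_average([])


class TestPeakAssignment:
    def test_upstream_window_overlap(self):
        # '+' gene at [1000, 2000): upstream window [0, 1000)
        gene = make_gene(1000, 2000, "+")
        peaks = [PeakCall(GenomicInterval("chr1", 200, 400))]
        assert assign_peaks_to_genes(peaks, [gene])["g"].bound

    def test_halfopen_boundary_not_bound(self):
        gene = make_gene(1000, 2000, "+")
        # window starts at 0 here; use a gene further in to probe the edge
        gene2 = make_gene(5000, 6000, "+", "g2")
        peaks = [PeakCall(GenomicInterval("chr1", 3900, 4000))]  # ends at tss-1000
        res = assign_peaks_to_genes(peaks, [gene, gene2])
        assert not res["g2"].bound

    def test_minus_strand_window_is_downstream_in_genome(self):
        gene = make_gene(1000, 2000, "-")
        inside = [PeakCall(GenomicInterval("chr1", 2500, 2600))]
        outside = [PeakCall(GenomicInterval("chr1", 3000, 3100))]
        assert assign_peaks_to_genes(inside, [gene])["g"].bound
        assert not assign_peaks_to_genes(outside, [gene])["g"].bound

    def test_matches_quadratic_oracle(self, rng):
        genes = []
        for i in range(60):
            s = int(rng.integers(0, 50_000))
            L = int(rng.integers(100, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(make_gene(s, s + L, strand, f"g{i}",
                                   chrom=f"chr{rng.integers(1, 3)}"))
        peaks = []
        for _ in range(150):
            s = int(rng.integers(0, 55_000))
            peaks.append(PeakCall(
                GenomicInterval(f"chr{rng.integers(1, 3)}", s,
                                s + int(rng.integers(50, 1500)))))
        got = assign_peaks_to_genes(peaks, genes, upstream_bp=1000)

        def window(g):
            if g.strand == "+":
                return max(g.interval.start - 1000, 0), g.interval.end
            return g.interval.start, g.interval.end + 1000

        for g in genes:
            w0, w1 = window(g)
            expect = {
                id(p) for p in peaks
                if p.interval.chrom == g.chrom
                and p.interval.start < w1 and w0 < p.interval.end
            }
            assert {id(p) for p in got[g.name].peaks} == expect
            assert got[g.name].bound == bool(expect)


class TestRankAndFilter:
    def test_identical_conditions_empty_at_threshold(self):
        s = {"a": 1.0, "b": 2.0, "c": 0.0}
        assert rank_and_filter(s, s, fold_threshold=1.5) == []

    def test_hand_enumerated_five_genes(self):
        # folds (eps=0): a=2.0, b=1.2, c=1.6, d=1.0, e=0.5 -> a, c pass 1.5
        ctrl = {"a": 1.0, "b": 5.0, "c": 2.5, "d": 3.0, "e": 4.0}
        treat = {"a": 2.0, "b": 6.0, "c": 4.0, "d": 3.0, "e": 2.0}
        got = rank_and_filter(ctrl, treat, fold_threshold=1.5, epsilon=0.0)
        assert [(r.gene_name, r.rank) for r in got] == [("a", 1), ("c", 2)]
        assert got[0].fold_ratio == pytest.approx(2.0)
        # ranking by treatment score instead puts c first
        got = rank_and_filter(ctrl, treat, fold_threshold=1.5, epsilon=0.0,
                              rank_by="score")
        assert [r.gene_name for r in got] == ["c", "a"]

    def test_threshold_monotonicity(self, rng):
        ctrl = {f"g{i}": float(rng.random() * 5 + 0.1) for i in range(50)}
        treat = {g: v * float(rng.random() * 3) for g, v in ctrl.items()}
        at_15 = {r.gene_name for r in rank_and_filter(ctrl, treat, fold_threshold=1.5)}
        at_20 = {r.gene_name for r in rank_and_filter(ctrl, treat, fold_threshold=2.0)}
        assert at_20 <= at_15

    def test_universe_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="x"):
            rank_and_filter({"a": 1, "x": 1}, {"a": 1, "y": 1})

    def test_both_zero_gives_ratio_one(self):
        got = rank_and_filter({"a": 0.0, "b": 1.0}, {"a": 0.0, "b": 9.0},
                              fold_threshold=1.5)
        ratios = {r.gene_name: r.fold_ratio for r in got}
        assert "a" not in ratios  # ratio exactly 1 never passes

    def test_bound_only_gate(self):
        ctrl, treat = {"a": 1.0, "b": 1.0}, {"a": 9.0, "b": 9.0}
        got = rank_and_filter(ctrl, treat, bound_only=True,
                              bound={"a": True, "b": False}, epsilon=0.0)
        assert [r.gene_name for r in got] == ["a"]

    def test_tie_break_by_name(self):
        ctrl, treat = {"z": 1.0, "m": 1.0}, {"z": 4.0, "m": 4.0}
        got = rank_and_filter(ctrl, treat, epsilon=0.0)
        assert [r.gene_name for r in got] == ["m", "z"]


class TestParameterRecovery:
    def test_fold_recovery_and_separation(self, default_track_sim):
        """Median recovered fold within 10% of 2 and enriched/non-enriched
        separation AUC >= 0.95 at defaults (200 genes, 1M reads)."""
        res = default_track_sim
        ctrl = normalize_track(res.control)
        treat = normalize_track(res.treatment)
        pc = polii.profile_genes(ctrl, res.genes)
        pt = polii.profile_genes(treat, res.genes)
        sa = {p.gene_name: enrichment_score(p) for p in pc}
        sb = {p.gene_name: enrichment_score(p) for p in pt}
        gt = res.ground_truth.set_index("gene")
        folds = {g: sb[g] / sa[g] for g in sa}  # all control scores positive
        enriched = [folds[g] for g in folds if gt.loc[g, "enriched"]]
        other = [folds[g] for g in folds if not gt.loc[g, "enriched"]]
        assert abs(np.median(enriched) - 2.0) / 2.0 < 0.10
        # separation AUC via the rank statistic
        pooled = np.array(enriched + other)
        labels = np.r_[np.ones(len(enriched)), np.zeros(len(other))]
        order = pooled.argsort()
        ranks = np.empty(len(pooled))
        ranks[order] = np.arange(1, len(pooled) + 1)
        n1, n0 = len(enriched), len(other)
        auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc >= 0.95
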