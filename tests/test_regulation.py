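"""Binding-to-transcription tests: TSS overlap and enrichment, TU-level RNAP
changes, direct-target calling, effector-modulation scoring, the six-mode
classifier, pileups, and clustering."""

import numpy as np
import pytest

from lrpmap import regulation, sim, tracks
from lrpmap.peakcall import PeakCall
from lrpmap.regulation import TSSAnnotation, TranscriptionUnit
from lrpmap.tracks import OccupancyTrack, SampleMeta


def peak(start, end):
    return PeakCall("rep1", start, end, start // 25, 5.0)


def tss(pos, strand="+", tu="tu1"):
    return TSSAnnotation(pos, strand, tu)


class TestOverlapTSS:
    def test_half_open_convention(self):
        p = [peak(100, 200)]
        assert regulation.overlap_tss(p, [tss(100)])[1] == 1.0   # start included
        assert regulation.overlap_tss(p, [tss(199)])[1] == 1.0
        assert regulation.overlap_tss(p, [tss(200)])[1] == 0.0   # end excluded

    def test_many_to_many_mapping(self):
        peaks = [peak(0, 500), peak(1000, 1200)]
        tsss = [tss(10, tu="a"), tss(20, tu="b"), tss(1100, tu="c")]
        mapping, fraction = regulation.overlap_tss(peaks, tsss)
        assert {t.tu_id for t in mapping[0]} == {"a", "b"}
        assert {t.tu_id for t in mapping[1]} == {"c"}
        assert fraction == 1.0

    def test_printed_novel_peak_fraction(self):
        """35 of 208 genotype-specific peaks at TSSs -> 16.8%."""
        peaks = [peak(i * 10_000, i * 10_000 + 300) for i in range(208)]
        tsss = [tss(i * 10_000 + 50, tu=f"tu{i}") for i in range(35)]
        _, fraction = regulation.overlap_tss(peaks, tsss)
        assert round(100 * fraction, 1) == 16.8


class TestTSSEnrichment:
    def test_full_coverage_peak_gives_p_one(self):
        p = [PeakCall("rep1", 0, 100_000, 0, 5.0)]
        observed, null, pval = regulation.tss_enrichment(
            p, [tss(500)], replicon_length=100_000, n_perm=99
        )
        assert observed == 1.0
        assert null.min() == 1.0
        assert pval == 1.0

    def test_no_tss_gives_observed_zero_p_one(self):
        observed, _, pval = regulation.tss_enrichment(
            [peak(0, 100)], [], replicon_length=100_000, n_perm=99
        )
        assert observed == 0.0 and pval == 1.0

    def test_planted_promoter_peaks_enriched(self, config, experiment):
        """Peaks planted at TSSs are detected as promoter-enriched."""
        tss_set, _, truth = experiment
        peaks = [
            PeakCall(sim.REPLICON, s.start, s.end, 0, 5.0)
            for s in truth.planted_sites if s.tu_id is not None
        ]
        _, _, pval = regulation.tss_enrichment(
            peaks, tss_set, config.genome_length, n_perm=999, seed=3
        )
        assert pval <= 0.01

    def test_rejects_zero_permutations(self):
        with pytest.raises(ValueError, match="n_perm"):
            regulation.tss_enrichment([peak(0, 10)], [tss(5)], 1000, n_perm=0)


def lr_track(values, genotype="WT", medium="Min"):
    return OccupancyTrack(
        "rep1", 25, np.asarray(values, float),
        SampleMeta(genotype, medium, "Log", assay="RNAP"), "log_ratio",
    )


class TestTuLog2FC:
    def test_identical_groups_give_zero(self):
        tu = TranscriptionUnit("tu1", 100, 600, "+")
        t = lr_track(np.ones(40))
        change = regulation.tu_log2fc([t, t], [t, t], tu)
        assert change.log2fc == 0.0

    def test_noiseless_planted_effect_recovered_exactly(self, experiment):
        """A +1 log2 planted effect comes back as exactly 1.0 without noise."""
        _, tus, truth = experiment
        cfg0 = sim.SimConfig(seed=11, noise_sd=0.0, lineage_sd=0.0)
        regulated = [
            tu for tu in tus if truth.tu_effects.get((tu.tu_id, "WT", "Min"), 0) != 0
        ]
        tu = regulated[0]
        truth.tu_effects[(tu.tu_id, "WT", "Min")] = 1.0
        geno, _ = sim.simulate_rnap_tracks(
            cfg0, truth, SampleMeta("WT", "Min", "Log", assay="RNAP"), tus
        )
        scar, _ = sim.simulate_rnap_tracks(
            cfg0, truth, SampleMeta("scar", "Min", "Log", assay="RNAP"), tus
        )
        inp = OccupancyTrack(sim.REPLICON, cfg0.bin_size,
                             np.full(geno.n_bins, cfg0.background_mean),
                             geno.meta, "raw")
        g_lr = tracks.log_ratio(geno, inp, pseudocount=1e-9, depth_normalize=False)
        s_lr = tracks.log_ratio(scar, inp, pseudocount=1e-9, depth_normalize=False)
        change = regulation.tu_log2fc([g_lr], [s_lr], tu)
        assert change.log2fc == pytest.approx(1.0, abs=1e-9)

    def test_recovered_vs_true_slope_near_one(self, experiment):
        """Across 100 TUs with N(0,1) planted effects and 4 replicates the
        regression of recovered on true effects has slope 1 +/- 0.1."""
        rng = np.random.default_rng(17)
        cfg = sim.SimConfig(seed=17, n_tus=100, n_primary_sites=40, genome_length=500_000)
        tss_set, tus, truth = sim.simulate_experiment(cfg)
        effects = rng.normal(size=len(tus))
        for tu, e in zip(tus, effects):
            truth.tu_effects[(tu.tu_id, "WT", "Min")] = float(e)

        def replicate_lr(genotype):
            out = []
            for lineage in (1, 2):
                for biorep in (1, 2):
                    meta = SampleMeta(genotype, "Min", "Log", lineage, biorep, "RNAP")
                    chip, inp = sim.simulate_rnap_tracks(cfg, truth, meta, tus)
                    out.append(tracks.log_ratio(chip, inp, pseudocount=0.5))
            return out

        g = regulation.tu_replicate_matrix(replicate_lr("WT"), tus)
        s = regulation.tu_replicate_matrix(replicate_lr("scar"), tus)
        recovered = g.mean(axis=0) - s.mean(axis=0)
        slope = np.polyfit(effects, recovered, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)


class TestDiffSignificance:
    def test_identical_groups_give_high_q(self):
        x = np.tile(np.arange(6.0), (4, 1))
        p, q = regulation.diff_significance(x, x, n_perm=199, seed=0)
        assert np.all(q > 0.9)

    def test_planted_effects_detected(self):
        """Large effects planted across most TUs reach q < 0.05 with 4v4
        replicates (the 4v4 permutation floor is 2/70, so BH needs a well-
        populated alternative, as a global regulator produces)."""
        rng = np.random.default_rng(1)
        n_tu, n_hit = 40, 30
        g = rng.normal(0, 0.1, size=(4, n_tu))
        s = rng.normal(0, 0.1, size=(4, n_tu))
        g[:, :n_hit] += 2.0
        p, q = regulation.diff_significance(g, s, n_perm=999, seed=1)
        assert np.all(q[:n_hit] < 0.05)
        # every planted effect sits at the discrete permutation floor
        assert np.all(p[:n_hit] <= 2 / 70 + 0.01)

    def test_bh_monotone_and_dominates_p(self):
        rng = np.random.default_rng(2)
        g = rng.normal(0, 1, size=(4, 30))
        s = rng.normal(0, 1, size=(4, 30))
        p, q = regulation.diff_significance(g, s, n_perm=199, seed=2)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDirectTargets:
    def test_binding_and_change_both_required(self):
        changes = [
            regulation.RNAPChange("bound_changed", ("Min", "Log"), 1.0, 0.1, q=0.01),
            regulation.RNAPChange("unbound_changed", ("Min", "Log"), 1.0, 0.1, q=0.01),
            regulation.RNAPChange("bound_flat", ("Min", "Log"), 0.0, 0.1, q=0.9),
        ]
        targets = regulation.call_direct_targets(
            ["bound_changed", "bound_flat"], changes, q_cut=0.05
        )
        assert targets == {"bound_changed"}


class TestLeucineModulationScore:
    @pytest.mark.parametrize(
        "fc_min,fc_liv,expected",
        [
            (2.0, 2.0, 0.0),     # unchanged effect
            (-2.0, 0.0, -2.0),   # weakened repression
            (1.0, 3.0, 2.0),     # strengthened activation
            (-1.0, -3.0, 2.0),   # strengthened repression
        ],
    )
    def test_sign_arithmetic(self, fc_min, fc_liv, expected):
        assert regulation.leucine_modulation_score(fc_min, fc_liv) == expected

    def test_antisymmetric_under_medium_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=2)
            s = np.sign(a)
            forward = (b - a) * s
            swapped = (a - b) * s
            assert forward == pytest.approx(-swapped)
            assert regulation.leucine_modulation_score(a, b) == pytest.approx(forward)


class TestClassifyMode:
    CASES = [
        # bound_min, bound_liv, fc_min, sig_min, fc_liv, sig_liv, expected
        (True, True, 2.0, True, 2.0, True, "independent_activating"),
        (True, True, -2.0, True, -2.0, True, "independent_repressing"),
        (True, True, 1.0, True, 3.0, True, "concerted_activating"),
        (True, True, -1.0, True, -3.0, True, "concerted_repressing"),
        (True, False, 2.0, True, 0.0, False, "reciprocal_activating"),
        (True, False, -2.0, True, 0.0, False, "reciprocal_repressing"),
        # magnitude reduction with binding retained is still reciprocal
        (True, True, 3.0, True, 1.0, True, "reciprocal_activating"),
        # effect appearing only in LIV is concerted
        (True, True, 0.0, False, 2.0, True, "concerted_activating"),
        # no significant effect anywhere -> unclassified
        (True, True, 0.1, False, 0.1, False, "unclassified"),
        # significant change without binding -> not a direct target
        (False, False, 2.0, True, 2.0, True, "unclassified"),
    ]

    @pytest.mark.parametrize("bm,bl,fm,sm,fl,sl,expected", CASES)
    def test_constructed_cases(self, bm, bl, fm, sm, fl, sl, expected):
        call = regulation.classify_mode(
            "tu1", bm, bl, fm, 0.1, sm, fl, 0.1, sl
        )
        assert call.mode == expected

    def test_leucine_only_reducing_binding_yields_only_reciprocal(self, experiment):
        """When the generative model lets leucine only reduce or abolish
        binding, every classified direct target is reciprocal."""
        _, tus, truth = experiment
        modes = set()
        for tu in tus:
            fc_min = truth.tu_effects.get((tu.tu_id, "WT", "Min"), 0.0)
            fc_liv = truth.tu_effects.get((tu.tu_id, "WT", "LIV"), 0.0)
            if fc_min == 0.0:
                continue
            site = next(s for s in truth.planted_sites if s.tu_id == tu.tu_id)
            call = regulation.classify_mode(
                tu.tu_id,
                bound_min=site.scales[("WT", "Min")] > 0,
                bound_liv=site.scales[("WT", "LIV")] > 0,
                fc_min=fc_min, se_min=0.02, sig_min=abs(fc_min) > 0.1,
                fc_liv=fc_liv, se_liv=0.02, sig_liv=abs(fc_liv) > 0.1,
            )
            modes.add(call.mode)
        assert modes <= {"reciprocal_activating", "reciprocal_repressing"}
        assert len(modes) == 2


class TestTssPileup:
    def track(self):
        values = np.zeros(400)
        values[100:110] = np.arange(10.0)
        return OccupancyTrack("rep1", 25, values, SampleMeta("WT", "Min", "Log"), "rz")

    def test_plus_strand_row_equals_window(self):
        t = self.track()
        row = regulation.tss_pileup(t, [tss(105 * 25)], half_width=250)[0]
        np.testing.assert_allclose(row, t.values[95:116])

    def test_minus_strand_row_reversed(self):
        t = self.track()
        plus = regulation.tss_pileup(t, [tss(105 * 25, "+")], half_width=250)[0]
        minus = regulation.tss_pileup(t, [tss(105 * 25, "-")], half_width=250)[0]
        np.testing.assert_allclose(minus, plus[::-1])

    def test_circular_wrap_at_origin(self):
        t = self.track()
        row = regulation.tss_pileup(t, [tss(0)], half_width=100)
        np.testing.assert_allclose(row[0], t.values[[-4, -3, -2, -1, 0, 1, 2, 3, 4]])

    def test_symmetric_peak_gives_symmetric_row(self, config, experiment, wt_min_subtracted):
        _, _, truth = experiment
        site = next(s for s in truth.sites_for("WT", "Min") if s.role == "primary")
        row = regulation.tss_pileup(
            wt_min_subtracted, [tss(site.center)], half_width=500
        )[0]
        # correlation between left and mirrored right halves is strongly positive
        k = len(row) // 2
        assert np.corrcoef(row[:k], row[k + 1 :][::-1])[0, 1] > 0.6


class TestClusterOrder:
    def test_identical_rows_merge_first(self):
        x = np.array([[5.0, 5.0], [0.0, 0.0], [5.0, 5.0]])
        order, Z = regulation.cluster_order(x)
        assert set(map(int, Z[0, :2])) == {0, 2}

    def test_one_dimensional_pairs_merge_before_final(self):
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        order, Z = regulation.cluster_order(x)
        first_two = {frozenset(map(int, Z[0, :2])), frozenset(map(int, Z[1, :2]))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @staticmethod
    def _cluster_sets(Z, n, relabel=None):
        """All merged clusters as frozensets of original leaf labels."""
        members = {i: frozenset([relabel[i] if relabel is not None else i])
                   for i in range(n)}
        out = set()
        for k, (a, b, *_rest) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.add(merged)
        return out

    def test_row_permutation_preserves_tree(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 5))
        perm = rng.permutation(8)
        _, Z1 = regulation.cluster_order(x)
        _, Z2 = regulation.cluster_order(x[perm])
        assert self._cluster_sets(Z1, 8) == self._cluster_sets(Z2, 8, relabel=perm)

    def test_column_axis(self):
        x = np.array([[0.0, 0.1, 9.0], [0.0, 0.2, 9.1]])
        order, Z = regulation.cluster_order(x, axis=1)
        assert set(map(int, Z[0, :2])) == {0, 1}
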