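import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribotempo import cub_models as cm
from ribotempo import orfeome_io as oi
from ribotempo import synthetic_data as sd
from ribotempo.genetics import FAMILY_OF, SENSE_CODONS


# --- independent oracle: explicit-loop %MinMax -----------------------------

def naive_minmax(codons, freq, left, right):
    """Brute-force %MinMax with explicit loops and no vectorization."""
    scores = [float("nan")] * len(codons)
    for i in range(len(codons)):
        if i - left < 0 or i + right >= len(codons):
            continue
        x_act = x_max = x_min = x_avg = 0.0
        size = left + right + 1
        for j in range(i - left, i + right + 1):
            fam = FAMILY_OF[codons[j]]
            vals = [freq[c] for c in fam]
            x_act += freq[codons[j]]
            x_max += max(vals)
            x_min += min(vals)
            x_avg += sum(vals) / len(vals)
        x_act, x_max, x_min, x_avg = (v / size for v in (x_act, x_max, x_min, x_avg))
        if x_act >= x_avg:
            scores[i] = (
                0.0 if x_max - x_avg <= 0 else 100.0 * (x_act - x_avg) / (x_max - x_avg)
            )
        else:
            scores[i] = -100.0 * (x_avg - x_act) / (x_avg - x_min)
    return scores


class TestWindowOffsets:
    def test_size_10_is_minus5_plus4(self):
        w = cm.window_offsets(10)
        assert (w.left, w.right) == (5, 4)

    def test_size_1_is_asite_only(self):
        assert cm.window_offsets(1) == cm.Window(0, 0)

    def test_special_window(self):
        assert cm.window_offsets(convention="special") == cm.Window(5, 3)

    @pytest.mark.parametrize("size", range(1, 22))
    def test_all_sizes_consistent(self, size):
        w = cm.window_offsets(size)
        assert w.size == size
        assert w.left == size // 2

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            cm.window_offsets(0)


class TestMinMaxTrack:
    def test_all_most_common_is_plus_100(self, small_tables):
        table = small_tables["orfeome"]
        best = {}
        for c in SENSE_CODONS:
            fam = FAMILY_OF[c]
            best[c] = max(fam, key=lambda x: table.freq[x])
        codons = tuple(best["GAT"] for _ in range(30))
        seq = oi.CodingSequence("g", codons)
        track = cm.minmax_track(seq, table, cm.Window(5, 4))
        assert np.allclose(track.scores[track.defined], 100.0)

    def test_all_least_common_is_minus_100(self, small_tables):
        table = small_tables["orfeome"]
        fam = FAMILY_OF["GAT"]
        worst = min(fam, key=lambda x: table.freq[x])
        seq = oi.CodingSequence("g", (worst,) * 30)
        track = cm.minmax_track(seq, table, cm.Window(5, 4))
        assert np.allclose(track.scores[track.defined], -100.0)

    def test_single_codon_window_hand_values(self):
        codons = ("GAC",) * 3 + ("GAT",) * 3
        table = oi.codon_family_frequencies(
            [oi.CodingSequence("ref", ("GAC",) * 7 + ("GAT",) * 3)]
        )
        assert math.isclose(table.freq["GAC"], 0.7)
        seq = oi.CodingSequence("g", codons)
        track = cm.minmax_track(seq, table, cm.Window(0, 0))
        # rarer codon: x_actual=0.3 = x_min < x_avg=0.5 -> -100
        assert np.allclose(track.scores[3:], -100.0)
        # most common codon: x_actual=0.7 = x_max -> +100
        assert np.allclose(track.scores[:3], 100.0)

    def test_matches_naive_oracle_on_random_genes(self, small_tables):
        table = small_tables["orfeome"]
        config = sd.SyntheticConfig(n_genes=20, length_range=(200, 202), seed=99)
        for seq in sd.gen_orfeome(config):
            track = cm.minmax_track(seq, table, cm.Window(5, 4))
            oracle = naive_minmax(seq.sense_codons, table.freq, 5, 4)
            np.testing.assert_allclose(
                track.scores, np.array(oracle), atol=1e-9, equal_nan=True
            )

    def test_degenerate_all_singleton_window_scores_zero(self, small_tables):
        seq = oi.CodingSequence("g", ("ATG", "TGG") * 5)
        track = cm.minmax_track(seq, small_tables["orfeome"], cm.Window(1, 1))
        assert np.allclose(track.scores[track.defined], 0.0)

    def test_window_larger_than_gene_all_undefined(self, small_tables):
        seq = oi.CodingSequence("g", ("GAT",) * 5)
        track = cm.minmax_track(seq, small_tables["orfeome"], cm.Window(5, 4))
        assert not track.defined.any()

    def test_antisymmetric_in_two_codon_family(self):
        table = oi.codon_family_frequencies(
            [oi.CodingSequence("ref", ("GAC",) * 6 + ("GAT",) * 4)]
        )
        win = cm.Window(2, 2)
        hi = cm.minmax_track(oi.CodingSequence("a", ("GAC",) * 11), table, win)
        lo = cm.minmax_track(oi.CodingSequence("b", ("GAT",) * 11), table, win)
        np.testing.assert_allclose(
            hi.scores[hi.defined], -lo.scores[lo.defined], atol=1e-9
        )

    def test_scores_bounded(self, small_orfeome, small_tables):
        for seq in small_orfeome[:10]:
            track = cm.minmax_track(seq, small_tables["orfeome"])
            defined = track.scores[track.defined]
            assert np.all(defined >= -100 - 1e-9)
            assert np.all(defined <= 100 + 1e-9)


class TestGeomeanTrack:
    def weights(self, mapping=None, default=1.0):
        w = {c: default for c in SENSE_CODONS}
        if mapping:
            w.update(mapping)
        return oi.AdaptivenessWeights("test", w)

    def test_identity_weights(self):
        seq = oi.CodingSequence("g", ("GAT",) * 20)
        track = cm.geomean_track(seq, self.weights(), cm.Window(5, 4))
        assert np.allclose(track.scores[track.defined], 1.0)

    def test_two_codon_geometric_mean(self):
        seq = oi.CodingSequence("g", ("GAT", "GAC") * 5)
        w = self.weights({"GAC": 0.25})
        track = cm.geomean_track(seq, w, cm.Window(0, 1))
        assert math.isclose(track.scores[0], 0.5)  # sqrt(1 * 0.25)

    def test_order_invariance(self):
        w = self.weights({"GAC": 0.25, "GAT": 0.7})
        a = cm.geomean_track(oi.CodingSequence("a", ("GAT", "GAC", "AAA")), w, cm.Window(0, 2))
        b = cm.geomean_track(oi.CodingSequence("b", ("AAA", "GAC", "GAT")), w, cm.Window(0, 2))
        assert math.isclose(a.scores[0], b.scores[0], rel_tol=1e-12)

    def test_singleton_exclusion(self):
        seq = oi.CodingSequence("g", ("ATG", "GAT", "TGG"))
        w = self.weights({"GAT": 0.3})
        track = cm.geomean_track(seq, w, cm.Window(0, 2), exclude_singletons=True)
        assert math.isclose(track.scores[0], 0.3)

    def test_all_singleton_window_undefined(self):
        seq = oi.CodingSequence("g", ("ATG", "TGG", "ATG"))
        track = cm.geomean_track(seq, self.weights(), cm.Window(0, 2))
        assert np.isnan(track.scores[0])

    @given(lam=st.floats(0.1, 1.0))
    @settings(max_examples=15, deadline=None)
    def test_scale_consistency(self, lam, small_orfeome, small_tables):
        base_w = small_tables["tai"]
        scaled = oi.AdaptivenessWeights(
            "scaled", {c: v * lam for c, v in base_w.w.items()}
        )
        seq = small_orfeome[0]
        a = cm.geomean_track(seq, base_w, cm.Window(5, 4))
        b = cm.geomean_track(seq, scaled, cm.Window(5, 4))
        np.testing.assert_allclose(
            b.scores[b.defined], lam * a.scores[a.defined], rtol=1e-9
        )

    def test_size_one_window_is_per_codon_function(self, small_orfeome, small_tables):
        w = small_tables["tai"]
        seq = small_orfeome[1]
        track = cm.geomean_track(seq, w, cm.Window(0, 0), exclude_singletons=False)
        expected = np.array([w.w[c] for c in seq.sense_codons])
        np.testing.assert_allclose(track.scores, expected, rtol=1e-12)


class TestBuildAllTracks:
    def test_five_models_equal_coverage(self, small_orfeome, small_tables):
        tracks = cm.build_all_tracks(
            small_orfeome,
            {"orfeome": small_tables["orfeome"], "high_phi": small_tables["high_phi"]},
            {k: small_tables[k] for k in ("cai", "highphi_cai", "tai")},
        )
        assert set(tracks) == set(cm.MODEL_NAMES)
        gene_sets = {frozenset(v) for v in tracks.values()}
        assert len(gene_sets) == 1

    def test_equal_tables_give_identical_tracks(self, small_orfeome, small_tables):
        table = small_tables["orfeome"]
        tracks = cm.build_all_tracks(
            small_orfeome,
            {"orfeome": table, "high_phi": table},
            {k: small_tables[k] for k in ("cai", "highphi_cai", "tai")},
        )
        for gene in tracks["orfeome_minmax"]:
            np.testing.assert_array_equal(
                tracks["orfeome_minmax"][gene].scores,
                tracks["highphi_minmax"][gene].scores,
            )

    def test_missing_table_fatal(self, small_orfeome, small_tables):
        with pytest.raises(KeyError, match="high_phi"):
            cm.build_all_tracks(
                small_orfeome,
                {"orfeome": small_tables["orfeome"]},
                {k: small_tables[k] for k in ("cai", "highphi_cai", "tai")},
            )

    def test_short_gene_present_all_undefined(self, small_tables):
        short = oi.CodingSequence("tiny", ("GAT",) * 4)
        tracks = cm.build_all_tracks(
            [short],
            {"orfeome": small_tables["orfeome"], "high_phi": small_tables["high_phi"]},
            {k: small_tables[k] for k in ("cai", "highphi_cai", "tai")},
        )
        assert not tracks["orfeome_minmax"]["tiny"].defined.any()


class TestCallSlow:
    def make_track(self, gene_id, scores):
        return cm.ModelTrack(gene_id, "m", np.asarray(scores, dtype=float), cm.Window(0, 0))

    def test_uniform_grid(self):
        track = self.make_track("g", np.arange(1.0, 101.0))
        calls = cm.call_slow([track], q=0.10)
        assert calls.labels["g"].sum() == 10
        assert calls.labels["g"][:10].all()

    def test_all_equal_all_slow(self):
        track = self.make_track("g", np.ones(50))
        calls = cm.call_slow([track], q=0.10)
        assert calls.labels["g"].all()

    def test_sort_based_oracle_with_ties(self, rng):
        scores = np.round(rng.normal(size=1000), 1)  # force ties
        calls = cm.call_slow([self.make_track("g", scores)], q=0.10)
        tau = np.quantile(scores, 0.10)
        expected = scores <= tau
        np.testing.assert_array_equal(calls.labels["g"], expected)
        # at least the 100 lowest are included
        assert calls.labels["g"].sum() >= 100

    def test_nan_positions_never_slow(self):
        scores = np.array([np.nan, -5.0, 0.0, np.nan, 1.0])
        calls = cm.call_slow([self.make_track("g", scores)], q=0.25)
        assert not calls.labels["g"][0] and not calls.labels["g"][3]

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            cm.call_slow([self.make_track("g", np.arange(10.0))], q=1.5)

    def test_pooled_across_genes(self):
        a = self.make_track("a", np.arange(0.0, 50.0))
        b = self.make_track("b", np.arange(50.0, 100.0))
        calls = cm.call_slow([a, b], q=0.10)
        assert calls.labels["a"].sum() == 10
        assert calls.labels["b"].sum() == 0
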