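import numpy as np
import pandas as pd
import pytest

from gpsccd import (
    CleavagePeptide,
    CleavageSite,
    Substrate,
    TrainingSet,
    build_training_set,
    calibrate_thresholds,
    load_blosum62,
    loo_scores,
    mam_optimize,
    mls_select,
    peptide_similarity,
    sn_at_sp,
    train_model,
)

from gpsccd.training import Model


def brute_force_sn_at_sp(pos, neg, sp_target):
    """Independent oracle: sweep every observed score plus a sentinel above
    the maximum; pick the smallest cutoff whose Sp reaches the target."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    candidates = sorted(set(pos) | set(neg)) + [max(pos.max(), neg.max()) + 1.0]
    for cutoff in candidates:
        sp = np.mean(neg < cutoff)
        if sp >= sp_target - 1e-12:
            return float(np.mean(pos >= cutoff)), float(cutoff)
    raise AssertionError("unreachable")


def make_ts(pos_residues, neg_residues):
    L = len(pos_residues[0])
    m, n = L - L // 2, L // 2
    mk = lambda seqs, tag: [
        CleavagePeptide(s, m, n, origin=(tag, i)) for i, s in enumerate(seqs)
    ]
    return TrainingSet(mk(pos_residues, "pos"), mk(neg_residues, "neg"), m, n)


class TestSnAtSp:
    def test_perfect_separation(self):
        res = sn_at_sp([10, 9, 8], [1, 2, 3], 0.9)
        assert res.sn == 1.0 and 3 < res.cutoff <= 8

    def test_tied_scores_resolved_by_rule(self):
        # no observed cutoff reaches Sp 0.5 -> sentinel above 5 -> Sn 0
        res = sn_at_sp([5.0], [5.0], 0.5)
        assert res.sn == 0.0 and res.cutoff > 5.0 and res.sp == 1.0

    def test_specificity_definition(self, rng):
        neg = rng.normal(size=100)
        pos = rng.normal(size=40) + 1
        res = sn_at_sp(pos, neg, 0.9)
        assert np.count_nonzero(neg < res.cutoff) >= 90
        assert res.sp >= 0.9

    def test_matches_brute_force_sweep(self, rng):
        """Random small integer-ish score sets: implementation equals the
        exhaustive cutoff sweep for several specificity targets."""
        for _ in range(50):
            pos = rng.integers(0, 12, size=rng.integers(2, 20)).astype(float)
            neg = rng.integers(0, 12, size=rng.integers(2, 30)).astype(float)
            for sp in (0.5, 0.85, 0.9, 0.95):
                got = sn_at_sp(pos, neg, sp)
                exp_sn, exp_cut = brute_force_sn_at_sp(pos, neg, sp)
                assert got.sn == exp_sn and got.cutoff == exp_cut


class TestLooScores:
    def test_two_identical_positives(self, blosum):
        ts = make_ts(["LKAA", "LKAA"], ["CCCC"])
        pos, neg = loo_scores(ts, blosum)
        self_sim = peptide_similarity("LKAA", "LKAA", blosum)
        assert pos[0] == pos[1] == self_sim

    def test_negative_duplicate_of_positive_scores_at_least_loo(self, blosum):
        """A negative identical to one of the positives sees the duplicate in
        its reference set; the positive itself does not (LOO)."""
        ts = make_ts(["LKAA", "WCDE", "PGHR"], ["LKAA"])
        pos, neg = loo_scores(ts, blosum)
        assert neg[0] >= pos[0]

    def test_order_invariance(self, blosum, small_training_set):
        ts = small_training_set
        shuffled = TrainingSet(
            list(reversed(ts.positives)), list(reversed(ts.negatives)), ts.m, ts.n
        )
        pos_a, neg_a = loo_scores(ts, blosum)
        pos_b, neg_b = loo_scores(shuffled, blosum)
        assert sorted(pos_a) == sorted(pos_b)
        assert sorted(neg_a) == sorted(neg_b)

    def test_single_positive_rejected(self, blosum):
        ts = make_ts(["LKAA"], ["CCCC"])
        with pytest.raises(ValueError, match="at least 2"):
            loo_scores(ts, blosum)

    def test_loo_matches_per_peptide_oracle(self, blosum, small_training_set):
        from gpsccd import prediction_score

        ts = small_training_set
        pos, neg = loo_scores(ts, blosum)
        for i in (0, len(ts.positives) - 1):
            p = ts.positives[i]
            assert pos[i] == prediction_score(
                p, ts.positives, blosum, exclude_origin=p.origin
            )
        for j in (0, len(ts.negatives) - 1):
            assert neg[j] == prediction_score(ts.negatives[j], ts.positives, blosum)


class TestMLS:
    def test_degenerate_grid_returns_cell(self, small_benchmark):
        substrates, sites = small_benchmark
        res = mls_select(substrates, sites, m_grid=[3], n_grid=[2])
        assert (res.m, res.n) == (3, 2)
        assert len(res.report) == 1

    def test_report_covers_grid_and_is_reproducible(self, small_benchmark):
        substrates, sites = small_benchmark
        r1 = mls_select(substrates, sites, m_grid=range(1, 4), n_grid=range(1, 3))
        r2 = mls_select(substrates, sites, m_grid=range(1, 4), n_grid=range(1, 3))
        assert len(r1.report) == 6
        pd.testing.assert_frame_equal(r1.report, r2.report)
        assert (r1.m, r1.n) == (r2.m, r2.n)

    def test_grid_cells_match_direct_loo(self, small_benchmark, blosum):
        """Every grid cell's Sn equals an independent evaluation: rebuild the
        training set at that window and run plain LOO + threshold search."""
        substrates, sites = small_benchmark
        res = mls_select(substrates, sites, m_grid=range(1, 4), n_grid=range(1, 3))
        for row in res.report.itertuples():
            ts = build_training_set(substrates, sites, row.m, row.n)
            pos, neg = loo_scores(ts, blosum)
            direct = sn_at_sp(pos, neg, 0.90)
            assert direct.sn == pytest.approx(row.sn)
            assert direct.cutoff == pytest.approx(row.cutoff)

    def test_planted_motif_window_selected(self):
        """Strong planted motif at P2/P1: the selected window must cover the
        strongly informative positions on every seed."""
        from gpsccd import default_calpain_profile, generate_benchmark

        for seed in range(3):
            substrates, sites = generate_benchmark(
                n_substrates=20,
                length_range=(80, 150),
                profile=default_calpain_profile(lam=1.0),
                rng_seed=seed,
            )
            res = mls_select(substrates, sites, m_grid=range(1, 6), n_grid=range(1, 4))
            assert res.m >= 2 and res.n >= 1


class TestMaM:
    def test_no_mutations_when_sn_saturated(self, blosum):
        ts = make_ts(["LKAA", "LKAA", "LKAC"], ["WWWW", "CCCC"])
        matrix, trace = mam_optimize(ts, blosum, 0.5, rng_seed=0, max_stale=20)
        assert len(trace) == 0
        assert matrix == blosum

    def test_trace_sn_strictly_increasing_and_final_ge_initial(self, small_training_set, blosum):
        ts = small_training_set
        pos0, neg0 = loo_scores(ts, blosum)
        sn0 = sn_at_sp(pos0, neg0, 0.90).sn
        matrix, trace = mam_optimize(ts, blosum, 0.90, rng_seed=3, max_stale=60)
        if len(trace):
            sns = np.concatenate([[trace.sn_before.iloc[0]], trace.sn_after.values])
            assert (np.diff(sns) > 0).all()
        pos1, neg1 = loo_scores(ts, matrix)
        assert sn_at_sp(pos1, neg1, 0.90).sn >= sn0

    def test_determinism_under_seed(self, small_training_set, blosum):
        ts = small_training_set
        m1, t1 = mam_optimize(ts, blosum, 0.90, rng_seed=11, max_stale=40)
        m2, t2 = mam_optimize(ts, blosum, 0.90, rng_seed=11, max_stale=40)
        assert m1 == m2
        pd.testing.assert_frame_equal(t1, t2)

    def test_pad_scores_untouched_by_training(self, small_training_set, blosum):
        matrix, _ = mam_optimize(small_training_set, blosum, 0.90, rng_seed=5, max_stale=40)
        assert not matrix.array[-1, :].any()
        assert not matrix.array[:, -1].any()

    def test_incremental_update_equals_full_recomputation(self, small_training_set, blosum):
        """The final trace Sn must equal a from-scratch LOO evaluation under
        the final matrix (the incremental bookkeeping is exact)."""
        ts = small_training_set
        matrix, trace = mam_optimize(ts, blosum, 0.90, rng_seed=7, max_stale=60)
        pos, neg = loo_scores(ts, matrix)
        full = sn_at_sp(pos, neg, 0.90).sn
        traced = trace.sn_after.iloc[-1] if len(trace) else sn_at_sp(
            *loo_scores(ts, blosum), 0.90
        ).sn
        assert full == pytest.approx(traced)

    def test_mutated_entries_are_plus_minus_one_steps(self, small_training_set, blosum):
        matrix, trace = mam_optimize(small_training_set, blosum, 0.90, rng_seed=9, max_stale=60)
        net = {}
        for row in trace.itertuples():
            net[(row.a, row.b)] = net.get((row.a, row.b), 0) + row.delta
        expected = {k: v for k, v in net.items() if v != 0}
        assert {(a, b): d for a, b, d in matrix.diff(blosum)} == expected


class TestCalibration:
    def test_perfect_separation_cutoffs_between_classes(self):
        cutoffs = calibrate_thresholds([10.0, 9.0, 8.0], [1.0, 2.0, 3.0])
        for c in cutoffs.values():
            assert 3.0 < c <= 8.0

    def test_nesting_invariant_on_random_sets(self, rng):
        for _ in range(30):
            pos = rng.normal(1, 1, size=rng.integers(3, 40))
            neg = rng.normal(0, 1, size=rng.integers(3, 60))
            c = calibrate_thresholds(pos, neg)
            assert c["high"] >= c["medium"] >= c["low"]


@pytest.fixture(scope="module")
def trained(small_benchmark):
    substrates, sites = small_benchmark
    return train_model(
        substrates,
        sites,
        m_grid=range(1, 5),
        n_grid=range(1, 3),
        max_stale=30,
        random_state=2,
    )


class TestTrainModel:

    def test_pipeline_outputs(self, trained):
        assert trained.cutoffs["high"] >= trained.cutoffs["medium"] >= trained.cutoffs["low"]
        assert "grid_report" in trained.training_log
        assert trained.label == "GPS-2.0-style"

    def test_no_mam_keeps_blosum62(self, small_benchmark):
        substrates, sites = small_benchmark
        model = train_model(
            substrates, sites, m_grid=range(1, 4), n_grid=range(1, 3), mam=False
        )
        assert model.matrix == load_blosum62()
        assert model.label == "GPS-1.1-style"

    def test_model_round_trip(self, trained, tmp_path):
        trained.save(tmp_path / "model")
        loaded = Model.load(tmp_path / "model")
        assert loaded.m == trained.m and loaded.n == trained.n
        assert loaded.matrix == trained.matrix
        assert loaded.cutoffs == trained.cutoffs
        assert [p.residues for p in loaded.positives] == [
            p.residues for p in trained.positives
        ]
        assert [p.origin for p in loaded.positives] == [
            p.origin for p in trained.positives
        ]

    def test_same_seed_byte_identical_model_files(self, small_benchmark, tmp_path):
        substrates, sites = small_benchmark
        for d in ("a", "b"):
            train_model(
                substrates,
                sites,
                m_grid=range(1, 4),
                n_grid=range(1, 3),
                max_stale=20,
                random_state=5,
            ).save(tmp_path / d)
        for name in ("model.json", "matrix.tsv", "positives.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
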