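import numpy as np
import pandas as pd
import pytest

from repfp import (
    ProbeProfile,
    SimParams,
    WindowMatrix,
    loess_smooth,
    normalize_scales,
    read_probe_profile,
    read_window_matrix,
    simulate_probe_profile,
    simulate_window_matrix,
    window_profiles,
    write_window_matrix,
)

from conftest import labels_for, make_matrix


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadProbeProfile:
    def test_bedgraph_basic(self, tmp_path):
        p = write(tmp_path, "a.bedgraph", "chr1 0 1000 1.5\nchr1 1000 2000 -0.5\n")
        prof = read_probe_profile(p)
        assert len(prof) == 2
        assert list(prof.records["value"]) == [1.5, -0.5]
        assert prof.sample_id == "a"

    def test_order_invariance(self, tmp_path):
        fwd = read_probe_profile(
            write(tmp_path, "f.bedgraph", "chr1 0 1000 1.5\nchr1 1000 2000 -0.5\n")
        )
        rev = read_probe_profile(
            write(tmp_path, "r.bedgraph", "chr1 1000 2000 -0.5\nchr1 0 1000 1.5\n"),
            sample_id="f",
        )
        assert fwd == rev

    def test_track_lines_skipped(self, tmp_path):
        p = write(tmp_path, "t.bedgraph", "track type=bedGraph\nchr1 0 10 1\n")
        assert len(read_probe_profile(p)) == 1

    def test_malformed_line_reports_location(self, tmp_path):
        p = write(tmp_path, "bad.bedgraph", "chr1 0 1000 1.5\nchr1 oops 2000 1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_probe_profile(p)

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no probe records"):
            read_probe_profile(write(tmp_path, "e.bedgraph", "\n"))

    def test_tsv3col_equals_bedgraph_downstream(self, tmp_path):
        """Midpoint-position TSV and its 1 bp bedGraph give equal windows."""
        rng = np.random.default_rng(5)
        pos = np.sort(rng.integers(0, 400_000, 60))
        vals = rng.normal(size=60)
        tsv = "\n".join(f"chr1\t{p}\t{v}" for p, v in zip(pos, vals))
        bg = "\n".join(f"chr1\t{p}\t{p + 1}\t{v}" for p, v in zip(pos, vals))
        prof_t = read_probe_profile(write(tmp_path, "x.tsv", tsv), format="tsv3col", sample_id="s")
        prof_b = read_probe_profile(write(tmp_path, "x.bedgraph", bg), sample_id="s")
        labels = labels_for({"s": "T"})
        mt = window_profiles([prof_t], labels, min_probes=1)
        mb = window_profiles([prof_b], labels, min_probes=1)
        pd.testing.assert_frame_equal(mt.values, mb.values)


class TestWindowProfiles:
    def test_single_window_mean(self, tmp_path):
        prof = ProbeProfile(
            "s",
            pd.DataFrame(
                {"chrom": "chr1", "start": [10_000, 50_000], "end": [10_050, 50_050],
                 "value": [2.0, 4.0]}
            ),
        )
        m = window_profiles([prof], labels_for({"s": "T"}), min_probes=1)
        assert m.values.iloc[0, 0] == pytest.approx(3.0)

    def test_min_probes_marks_missing(self):
        prof = ProbeProfile(
            "s",
            pd.DataFrame(
                {"chrom": "chr1", "start": [10, 20, 250_000], "end": [11, 21, 250_001],
                 "value": [1.0, 2.0, 3.0]}
            ),
        )
        m = window_profiles([prof], labels_for({"s": "T"}), min_probes=2)
        assert m.values.iloc[0, 0] == pytest.approx(1.5)
        assert np.isnan(m.values.iloc[1, 0])

    def test_window_means_match_brute_force(self):
        """Random probes across two windows equal a per-window mean oracle."""
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 400_000, 40)
        vals = rng.normal(size=40)
        prof = ProbeProfile(
            "s",
            pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1, "value": vals}),
        )
        m = window_profiles([prof], labels_for({"s": "T"}), min_probes=1)
        mids = starts + 0.5
        for w in range(2):
            mask = (mids >= w * 200_000) & (mids < (w + 1) * 200_000)
            if mask.sum():
                assert m.values.iloc[w, 0] == pytest.approx(vals[mask].mean(), abs=1e-12)

    def test_split_interval_invariance(self):
        """Splitting a bedGraph interval into equal-value halves changes nothing."""
        whole = ProbeProfile(
            "s", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "value": [2.0]})
        )
        halves = ProbeProfile(
            "s",
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [500, 1000],
                 "value": [2.0, 2.0]}
            ),
        )
        m1 = window_profiles([whole], labels_for({"s": "T"}), min_probes=1)
        m2 = window_profiles([halves], labels_for({"s": "T"}), min_probes=1)
        assert m1.values.iloc[0, 0] == m2.values.iloc[0, 0] == 2.0

    def test_missing_chromosome_warns(self):
        p1 = ProbeProfile("a", pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1], "value": [1.0]}))
        p2 = ProbeProfile(
            "b",
            pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 0], "end": [1, 1], "value": [1.0, 2.0]}),
        )
        with pytest.warns(UserWarning, match="chr2"):
            m = window_profiles([p1, p2], labels_for({"a": "T", "b": "T"}), min_probes=1)
        chr2_rows = m.windows["chrom"] == "chr2"
        assert m.values.loc[chr2_rows.to_numpy(), "a"].isna().all()


class TestNormalizeScales:
    def test_zscore_basic(self):
        m = make_matrix({"s": [1.0, 2.0, 3.0], "t": [1.0, 2.0, 4.0]},
                        labels_for({"s": "A", "t": "B"}))
        out = normalize_scales(m, method="zscore")
        assert list(out.values["s"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_zscore_idempotent_and_scale_free(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=20)
        m1 = make_matrix({"s": list(vals), "t": list(rng.normal(size=20))},
                         labels_for({"s": "A", "t": "B"}))
        m10 = make_matrix({"s": list(10 * vals), "t": list(m1.values["t"])},
                          labels_for({"s": "A", "t": "B"}))
        out1 = normalize_scales(m1, method="zscore")
        out10 = normalize_scales(m10, method="zscore")
        np.testing.assert_allclose(out1.values.to_numpy(), out10.values.to_numpy(), atol=1e-12)
        again = normalize_scales(out1, method="zscore")
        np.testing.assert_allclose(again.values.to_numpy(), out1.values.to_numpy(), atol=1e-12)

    def test_zscore_reference_mapping(self):
        m = make_matrix({"s": [1.0, 2.0, 3.0], "t": [0.0, 1.0, 2.0]},
                        labels_for({"s": "A", "t": "B"}))
        out = normalize_scales(m, method="zscore", reference=(5.0, 2.0))
        assert out.values["s"].mean() == pytest.approx(5.0)
        assert out.values["s"].std(ddof=1) == pytest.approx(2.0)

    def test_zero_spread_names_sample(self):
        m = make_matrix({"s": [1.0, 1.0], "t": [0.0, 1.0]}, labels_for({"s": "A", "t": "B"}))
        with pytest.raises(ValueError, match="'s'"):
            normalize_scales(m, method="zscore")

    def test_quantile_matches_rank_average_oracle(self):
        # hand oracle: ref = mean of sorted columns; each value takes the
        # ref value at its rank (average rank on ties)
        a = [5.0, 2.0, 3.0, 4.0, 1.0]
        b = [4.0, 1.0, 4.0, 2.0, 3.0]
        m = make_matrix({"s": a, "t": b}, labels_for({"s": "A", "t": "B"}))
        out = normalize_scales(m, method="quantile")
        ref = (np.sort(a) + np.sort(b)) / 2
        expected_s = ref[np.argsort(np.argsort(a))]
        np.testing.assert_allclose(out.values["s"].to_numpy(), expected_s)
        # tied values in t share the average of their reference positions
        expected_t = np.array([(ref[3] + ref[4]) / 2, ref[0], (ref[3] + ref[4]) / 2, ref[1], ref[2]])
        np.testing.assert_allclose(out.values["t"].to_numpy(), expected_t)

    def test_quantile_equalizes_tie_free_columns(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=8), rng.normal(size=8)
        m = make_matrix({"s": list(a), "t": list(b)}, labels_for({"s": "A", "t": "B"}))
        out = normalize_scales(m, method="quantile")
        np.testing.assert_allclose(
            np.sort(out.values["s"].to_numpy()), np.sort(out.values["t"].to_numpy())
        )


class TestLoess:
    @staticmethod
    def probes(x, y):
        return ProbeProfile(
            "s", pd.DataFrame({"chrom": "chr1", "start": x, "end": x + 100, "value": y})
        )

    def test_constant_preserved(self):
        x = np.sort(np.random.default_rng(0).integers(0, 5_000_000, 300))
        sm = loess_smooth(self.probes(x, np.full(300, 1.7)))
        np.testing.assert_allclose(sm.records["value"], 1.7)

    def test_linear_exact(self):
        x = np.sort(np.random.default_rng(1).integers(0, 5_000_000, 300))
        y = 3e-7 * (x + 50) - 1.0
        sm = loess_smooth(self.probes(x, y))
        np.testing.assert_allclose(sm.records["value"].to_numpy(), y, atol=1e-9)

    def test_noisy_sine_matches_local_regression_oracle(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.integers(0, 10_000_000, 800))
        mid = x + 50
        truth = np.sin(2 * np.pi * mid / 4_000_000)
        y = truth + rng.normal(0, 0.3, size=len(x))
        sm = loess_smooth(self.probes(x, y), span_bp=300_000)
        # independent oracle: plain numpy weighted quadratic on the same neighborhoods
        from repfp.profile_io import _neighborhood_size, _nearest_window

        k = _neighborhood_size(mid.astype(float), 300_000, k_min=4)
        oracle = np.empty(len(x))
        for i in range(len(x)):
            lo, hi = _nearest_window(mid.astype(float), i, k)
            xs, ys = mid[lo:hi].astype(float), y[lo:hi]
            d = np.abs(xs - mid[i])
            w = (1 - (d / d.max()) ** 3) ** 3
            W = np.diag(w)
            X = np.stack([np.ones_like(xs), xs - mid[i], (xs - mid[i]) ** 2], axis=1)
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys)
            oracle[i] = beta[0]
        rms = np.sqrt(np.mean((sm.records["value"].to_numpy() - oracle) ** 2))
        assert rms < 0.05

    def test_span_below_spacing_errors(self):
        x = np.arange(0, 10) * 1_000_000
        with pytest.raises(ValueError, match="span"):
            loess_smooth(self.probes(x, np.ones(10)), span_bp=1000)


class TestMatrixIO:
    def test_round_trip_with_missing(self, tmp_path):
        matrix, _ = simulate_window_matrix(SimParams(n_windows=60, n_diff_blocks=2, block_len=1, seed=4))
        v = matrix.values.copy()
        v.iloc[5, 1] = np.nan
        matrix = WindowMatrix(matrix.windows, matrix.labels, v)
        path = tmp_path / "m.tsv"
        write_window_matrix(matrix, path)
        back = read_window_matrix(path)
        pd.testing.assert_frame_equal(back.windows, matrix.windows)
        pd.testing.assert_frame_equal(back.labels, matrix.labels)
        pd.testing.assert_frame_equal(back.values, matrix.values)
        pd.testing.assert_frame_equal(back.missing_mask, matrix.missing_mask)

    def test_byte_stable(self, tmp_path):
        matrix, _ = simulate_window_matrix(SimParams(n_windows=1000, n_diff_blocks=12, block_len=1, seed=5))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_window_matrix(matrix, p1)
        write_window_matrix(read_window_matrix(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestProbeSimRoundTrip:
    def test_noiseless_probes_recover_window_values(self):
        matrix, _ = simulate_window_matrix(SimParams(n_windows=40, n_diff_blocks=1, block_len=1, seed=6))
        sid = matrix.sample_ids[0]
        prof = simulate_probe_profile(
            matrix.windows, matrix.values[sid].to_numpy(), sample_id=sid, seed=1
        )
        m2 = window_profiles([prof], matrix.labels.iloc[[0]], min_probes=1)
        np.testing.assert_allclose(
            m2.values[sid].to_numpy(), matrix.values[sid].to_numpy(), atol=1e-12
        )

    def test_noisy_probes_recover_within_standard_error(self):
        matrix, _ = simulate_window_matrix(SimParams(n_windows=40, n_diff_blocks=1, block_len=1, seed=6))
        sid = matrix.sample_ids[0]
        prof = simulate_probe_profile(
            matrix.windows,
            matrix.values[sid].to_numpy(),
            sample_id=sid,
            probes_per_window=(100, 100),
            probe_noise_sd=0.3,
            seed=2,
        )
        m2 = window_profiles([prof], matrix.labels.iloc[[0]], min_probes=1)
        # 0.3 / sqrt(100) = 0.03 SE; 0.1 is ~3 SE
        assert np.abs(m2.values[sid].to_numpy() - matrix.values[sid].to_numpy()).max() < 0.1

    def test_seed_determinism(self):
        matrix, _ = simulate_window_matrix(SimParams(n_windows=20, n_diff_blocks=1, block_len=1, seed=6))
        a = simulate_probe_profile(matrix.windows, matrix.values.iloc[:, 0].to_numpy(), seed=3)
        b = simulate_probe_profile(matrix.windows, matrix.values.iloc[:, 0].to_numpy(), seed=3)
        assert a == b
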