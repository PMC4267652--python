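"""Window counting, median-ratio normalization, filtering, log/z."""

import numpy as np
import pandas as pd
import pytest

import chromnet as cn
from conftest import make_raw_matrix

CHIP_ROLES = {"t1": "CM", "t2": "HM", "input": "input"}


# -- window counting -------------------------------------------------------

def test_no_reads_gives_zero_matrix():
    windows = [cn.GenomicWindow("chr1", 0, 4000, gene_id="g1")]
    sm = cn.count_reads_in_windows(
        {"t1": [], "t2": [], "input": []}, windows, CHIP_ROLES
    )
    assert (sm.data.to_numpy() == 0).all()
    assert sm.state == "raw_counts"


def test_half_open_window_boundaries():
    windows = [cn.GenomicWindow("chr1", 100, 200, gene_id="g1")]
    sm = cn.count_reads_in_windows(
        {"t1": [("chr1", 100), ("chr1", 200), ("chr1", 199)],
         "input": []},
        windows,
        {"t1": "CM", "input": "input"},
    )
    assert sm.data.loc["g1", "t1"] == 2  # start included, end excluded


def test_window_counts_match_per_read_oracle():
    """Vectorized counting equals a brute-force per-read membership loop."""
    rng = np.random.default_rng(5)
    positions = [("chr1", int(p)) for p in rng.integers(0, 10_000, size=100)]
    windows = [
        cn.GenomicWindow("chr1", 3000, 7000, gene_id="g1"),
        cn.GenomicWindow("chr1", 6000, 10_000, gene_id="g2"),  # overlaps g1
    ]
    sm = cn.count_reads_in_windows(
        {"t1": positions, "input": positions},
        windows,
        {"t1": "CM", "input": "input"},
    )
    for w in windows:
        expected = sum(1 for _, p in positions if w.start <= p < w.end)
        assert sm.data.loc[w.gene_id, "t1"] == expected


def test_reads_on_unknown_chromosome_count_zero(caplog):
    windows = [cn.GenomicWindow("chr1", 0, 4000, gene_id="g1")]
    with caplog.at_level("WARNING"):
        sm = cn.count_reads_in_windows(
            {"t1": [("chrUn", 5)], "input": []}, windows,
            {"t1": "CM", "input": "input"},
        )
    assert sm.data.loc["g1", "t1"] == 0
    assert any("chromosomes without windows" in r.message for r in caplog.records)


# -- normalization ---------------------------------------------------------

def test_sample_equal_input_normalizes_to_one():
    sm = make_raw_matrix(
        {"t1": [3, 7, 0], "t2": [1, 1, 1], "input": [3, 7, 0]},
        CHIP_ROLES,
    )
    out = cn.median_ratio_normalize(sm)
    np.testing.assert_allclose(out.data["t1"], 1.0)
    assert out.norm_factors["t1"] == 1.0


def test_exact_proportionality_normalizes_to_one():
    c = np.array([1, 4, 0])
    s = 3 * (c + 1) - 1  # (S+1) = 3 (C+1)
    sm = make_raw_matrix({"t1": s, "input": c}, {"t1": "CM", "input": "input"})
    out = cn.median_ratio_normalize(sm)
    assert out.norm_factors["t1"] == pytest.approx(3.0)
    np.testing.assert_allclose(out.data["t1"], 1.0)


def test_normalization_hand_example():
    """S=[0,9,4], C=[1,4,0]: ratios [0.5,2,5], m=2, S_norm=[0.25,1,2.5]."""
    sm = make_raw_matrix(
        {"t1": [0, 9, 4], "input": [1, 4, 0]}, {"t1": "CM", "input": "input"}
    )
    out = cn.median_ratio_normalize(sm)
    assert out.norm_factors["t1"] == pytest.approx(2.0)
    np.testing.assert_allclose(out.data["t1"], [0.25, 1.0, 2.5])


def test_normalization_scale_invariance():
    """Scaling (S+1) by an integer k leaves S_norm unchanged: m absorbs k."""
    rng = np.random.default_rng(8)
    c = rng.integers(0, 50, size=41)
    s = rng.integers(0, 80, size=41)
    k = 3
    scaled = k * (s + 1) - 1
    roles = {"t1": "CM", "input": "input"}
    out = cn.median_ratio_normalize(make_raw_matrix({"t1": s, "input": c}, roles))
    out_k = cn.median_ratio_normalize(
        make_raw_matrix({"t1": scaled, "input": c}, roles)
    )
    np.testing.assert_allclose(out_k.data["t1"], out.data["t1"])
    assert out_k.norm_factors["t1"] == pytest.approx(k * out.norm_factors["t1"])


def test_expression_tracks_pass_through_unnormalized():
    sm = make_raw_matrix(
        {"t1": [5, 1], "expr": [10, 0], "input": [1, 1]},
        {"t1": "CM", "expr": "expression", "input": "input"},
    )
    out = cn.median_ratio_normalize(sm)
    np.testing.assert_array_equal(out.data["expr"], [10, 0])
    assert "expr" not in out.norm_factors
    assert "input" not in out.data.columns


def test_normalize_empty_matrix_errors():
    sm = make_raw_matrix({"t1": [], "input": []}, {"t1": "CM", "input": "input"})
    with pytest.raises(cn.ParameterError):
        cn.median_ratio_normalize(sm)


# -- promoter filtering ----------------------------------------------------

def test_all_zero_counts_removes_every_promoter():
    sm = make_raw_matrix(
        {"t1": [0, 0], "t2": [0, 0], "input": [0, 0]}, CHIP_ROLES
    )
    assert len(cn.filter_promoters(sm).data) == 0


def test_sample_above_input_is_retained():
    sm = make_raw_matrix({"t1": [5], "t2": [0], "input": [3]}, CHIP_ROLES)
    assert cn.filter_promoters(sm).promoter_ids == ["p0"]


def test_filter_matches_row_scan_oracle():
    """Vectorized filter equals an explicit promoter-by-track double loop."""
    rng = np.random.default_rng(9)
    counts = {f"t{j}": rng.integers(0, 6, size=50) for j in range(5)}
    counts["input"] = rng.integers(0, 6, size=50)
    roles = {f"t{j}": ("HM" if j % 2 else "CM") for j in range(5)}
    roles["input"] = "input"
    sm = make_raw_matrix(counts, roles)
    kept = cn.filter_promoters(sm).promoter_ids
    expected = [
        f"p{i}"
        for i in range(50)
        if any(counts[f"t{j}"][i] > counts["input"][i] for j in range(5))
    ]
    assert kept == expected


def test_filter_ignores_expression_tracks():
    sm = make_raw_matrix(
        {"t1": [0], "expr": [99], "input": [5]},
        {"t1": "CM", "expr": "expression", "input": "input"},
    )
    assert len(cn.filter_promoters(sm).data) == 0


def test_filter_is_idempotent():
    rng = np.random.default_rng(10)
    sm = make_raw_matrix(
        {"t1": rng.integers(0, 4, 30), "t2": rng.integers(0, 4, 30),
         "input": rng.integers(0, 4, 30)},
        CHIP_ROLES,
    )
    once = cn.filter_promoters(sm)
    twice = cn.filter_promoters(once)
    assert once.data.equals(twice.data)


# -- replicate averaging ---------------------------------------------------

def test_identical_replicates_average_to_themselves():
    sm = make_raw_matrix(
        {"r1": [4, 2], "r2": [4, 2], "input": [1, 1]},
        {"r1": "expression", "r2": "expression", "input": "input"},
    )
    out = cn.average_replicates(sm, {"expr": ["r1", "r2"]})
    np.testing.assert_array_equal(out.data["expr"], [4, 2])
    assert out.roles["expr"] == "expression"


def test_replicate_mean_is_arithmetic():
    sm = make_raw_matrix(
        {"r1": [2], "r2": [4], "input": [1]},
        {"r1": "expression", "r2": "expression", "input": "input"},
    )
    out = cn.average_replicates(sm, {"expr": ["r1", "r2"]})
    assert out.data["expr"].iloc[0] == pytest.approx(3.0)


def test_replicate_average_matches_row_mean_oracle():
    rng = np.random.default_rng(11)
    counts = {f"r{j}": rng.integers(0, 100, 20) for j in range(3)}
    counts["input"] = rng.integers(0, 100, 20)
    roles = {f"r{j}": "expression" for j in range(3)}
    roles["input"] = "input"
    sm = make_raw_matrix(counts, roles)
    out = cn.average_replicates(sm, {"expr": ["r0", "r1", "r2"]})
    expected = [
        (counts["r0"][i] + counts["r1"][i] + counts["r2"][i]) / 3
        for i in range(20)
    ]
    np.testing.assert_allclose(out.data["expr"], expected)


def test_track_in_two_groups_rejected():
    sm = make_raw_matrix(
        {"r1": [1], "r2": [1], "input": [1]},
        {"r1": "expression", "r2": "expression", "input": "input"},
    )
    with pytest.raises(cn.ParameterError):
        cn.average_replicates(sm, {"g1": ["r1"], "g2": ["r1", "r2"]})


# -- log/z transform -------------------------------------------------------

def test_standardized_columns_have_zero_mean_unit_sd(standardized):
    values = standardized.data.to_numpy()
    assert np.abs(values.mean(axis=0)).max() < 1e-10
    np.testing.assert_allclose(values.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_log_standardize_hand_example():
    """Column [e, e^2, e^3] -> logs [1,2,3] -> z-scores [-1, 0, 1] (n-1 SD)."""
    e = np.e
    data = pd.DataFrame({"t1": [e, e**2, e**3]}, index=["p0", "p1", "p2"])
    sm = cn.SignalMatrix(
        data=data, roles={"t1": "CM"}, state="normalized",
        norm_factors={"t1": 1.0},
    )
    out = cn.log_standardize(sm)
    np.testing.assert_allclose(out.data["t1"], [-1.0, 0.0, 1.0], atol=1e-12)


def test_constant_column_raises_degenerate_error():
    data = pd.DataFrame({"t1": [2.0, 2.0, 2.0]}, index=["p0", "p1", "p2"])
    sm = cn.SignalMatrix(data=data, roles={"t1": "CM"}, state="normalized")
    with pytest.raises(cn.DegenerateTrackError, match="t1"):
        cn.log_standardize(sm)


# -- state machine and I/O -------------------------------------------------

def test_pipeline_order_is_enforced(fixture_pair):
    _, sm_a, _ = fixture_pair
    with pytest.raises(cn.StateError):
        cn.log_standardize(sm_a)  # raw, not normalized
    normalized = cn.median_ratio_normalize(cn.filter_promoters(sm_a))
    with pytest.raises(cn.StateError):
        cn.filter_promoters(normalized)
    with pytest.raises(cn.StateError):
        cn.median_ratio_normalize(normalized)


def test_raw_matrix_requires_exactly_one_input_track():
    data = pd.DataFrame({"t1": [1]}, index=["p0"])
    with pytest.raises(cn.SchemaError):
        cn.SignalMatrix(data=data, roles={"t1": "CM"}, state="raw_counts")


def test_tsv_round_trip(tmp_path, fixture_pair):
    _, sm_a, _ = fixture_pair
    sm_a.to_tsv(tmp_path / "m.tsv", tmp_path / "m.yaml")
    back = cn.read_signal_matrix(tmp_path / "m.tsv", tmp_path / "m.yaml")
    assert back.roles == sm_a.roles
    assert back.state == sm_a.state
    np.testing.assert_array_equal(back.data.to_numpy(), sm_a.data.to_numpy())


def test_bed_round_trip(tmp_path):
    windows = [
        cn.GenomicWindow("chr1", 1000, 5000, "+", "g1"),
        cn.GenomicWindow("chr2", 0, 4000, "-", "g2"),
    ]
    cn.write_bed_windows(windows, tmp_path / "w.bed")
    assert cn.read_bed_windows(tmp_path / "w.bed") == windows
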