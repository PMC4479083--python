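"""Data containers, clinical-grouping rules and the TSV/GMT readers."""

import numpy as np
import pandas as pd
import pytest

from serialdex import (
    CentroidPanel,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    has_residual_disease,
    percent_rounded,
    rcb_group,
    read_centroids,
    read_expression,
    read_gmt,
    read_sample_meta,
    validate_sample_meta,
    write_centroids,
    write_expression,
    write_gmt,
    write_sample_meta,
)


@pytest.mark.parametrize(
    "rcb,expected",
    [
        ("0", "responder"),
        ("I", "responder"),
        ("II", "nonresponder"),
        ("III", "nonresponder"),
        ("undetermined", "NA"),
        (None, "NA"),
        (float("nan"), "NA"),
    ],
)
def test_rcb_group_total_mapping(rcb, expected):
    """RCB 0/I are responders, II/III nonresponders; the map is total."""
    assert rcb_group(rcb) == expected


@pytest.mark.parametrize(
    "rcb,eligible",
    [("0", False), ("I", True), ("II", True), ("III", True), ("undetermined", False), (None, False)],
)
def test_residual_disease_includes_rcb_one(rcb, eligible):
    """Surgical-specimen analyses include RCB I/II/III (residual disease)."""
    assert has_residual_disease(rcb) is eligible


def test_percent_rounding_half_away_from_zero():
    assert percent_rounded(27, 36) == 75
    assert percent_rounded(24, 39) == 62  # 61.53 -> 62
    assert percent_rounded(1, 8) == 13    # 12.5 rounds away from zero


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


def test_read_expression_parses_values_and_missing(tmp_path):
    p = _write(tmp_path / "e.tsv", "feature_id\ts1\ts2\ng1\t1.5\t-0.5\ng2\tNA\t0\n")
    m = read_expression(p)
    assert m.shape == (2, 2)
    assert m.data.loc["g1", "s1"] == 1.5
    assert np.isnan(m.data.loc["g2", "s1"])
    assert m.data.loc["g2", "s2"] == 0.0  # missing is distinct from zero


def test_read_expression_rejects_duplicates_and_bad_cells(tmp_path):
    dup = _write(tmp_path / "dup.tsv", "feature_id\ts1\ts1\ng1\t1\t2\n")
    with pytest.raises(FormatError, match="s1"):
        read_expression(dup)
    dupf = _write(tmp_path / "dupf.tsv", "feature_id\ts1\ng1\t1\ng1\t2\n")
    with pytest.raises(FormatError, match="g1"):
        read_expression(dupf)
    bad = _write(tmp_path / "bad.tsv", "feature_id\ts1\ts2\ng1\t1.0\tabc\n")
    with pytest.raises(FormatError, match="abc"):
        read_expression(bad)


def test_expression_roundtrip_lossless(tmp_path, rng):
    values = pd.DataFrame(
        rng.standard_normal((5, 4)), index=[f"g{i}" for i in range(5)], columns=[f"s{j}" for j in range(4)]
    )
    values.iloc[2, 1] = np.nan
    m = ExpressionMatrix(values, level="gene")
    path = tmp_path / "m.tsv"
    write_expression(m, path)
    back = read_expression(path)
    pd.testing.assert_frame_equal(back.data, m.data, check_names=False)


def test_sample_meta_derives_group_and_roundtrips(tmp_path):
    p = _write(
        tmp_path / "s.tsv",
        "sample_id\tpatient_id\ttimepoint\tbatch\trcb\thr_status\trfs_time\trfs_event\n"
        "a\tP1\tT1\tB1\tII\tpositive\t12.5\t1\n"
        "b\tP1\tT2\tB2\t0\tpositive\t12.5\t1\n"
        "c\tP2\tT1\tB1\t\tNA\tNA\tNA\n",
    )
    meta = read_sample_meta(p)
    assert meta.loc["a", "rcb_group"] == "nonresponder"
    assert meta.loc["b", "rcb_group"] == "responder"
    assert meta.loc["c", "rcb_group"] == "NA"
    out = tmp_path / "s2.tsv"
    write_sample_meta(meta, out)
    pd.testing.assert_frame_equal(read_sample_meta(out), meta)


def test_sample_meta_invariants():
    base = {
        "sample_id": ["a", "b"],
        "patient_id": ["P1", "P1"],
        "timepoint": ["T1", "T1"],
        "batch": ["B1", "B1"],
    }
    with pytest.raises(FormatError, match="patient, timepoint"):
        validate_sample_meta(pd.DataFrame(base))
    bad_tp = dict(base, timepoint=["T1", "T9"])
    with pytest.raises(FormatError, match="T9"):
        validate_sample_meta(pd.DataFrame(bad_tp))
    with pytest.raises(FormatError, match="rfs_event"):
        validate_sample_meta(
            pd.DataFrame(dict(base, timepoint=["T1", "T2"], rfs_event=[1, 0]))
        )
    with pytest.raises(FormatError, match="rfs_time"):
        validate_sample_meta(
            pd.DataFrame(dict(base, timepoint=["T1", "T2"], rfs_time=[0.0, 5.0], rfs_event=[1, 0]))
        )


def test_gmt_parse_dedup_and_errors(tmp_path):
    p = _write(tmp_path / "x.gmt", "CC\tdesc\tAURKA\tPLK1\tCENPF\n")
    gmt = read_gmt(p)
    assert gmt.sets["CC"] == ["AURKA", "PLK1", "CENPF"]
    dup = _write(tmp_path / "d.gmt", "CC\tdesc\taurka\tAURKA\tPLK1\n")
    with pytest.warns(UserWarning, match="dedup"):
        gmt = read_gmt(dup)
    assert gmt.sets["CC"] == ["AURKA", "PLK1"]  # case-folded and deduplicated
    empty = _write(tmp_path / "e.gmt", "CC\tdesc\t\n")
    with pytest.raises(FormatError):
        read_gmt(empty)
    roundtrip = tmp_path / "r.gmt"
    write_gmt(gmt, roundtrip)
    assert read_gmt(roundtrip).sets == gmt.sets


def test_centroid_panel_roundtrip_and_errors(tmp_path):
    df = pd.DataFrame({"LumA": [1.0, 2.0], "Basal": [-1.0, 0.5]}, index=["AURKA", "ESR1"])
    panel = CentroidPanel(df)
    path = tmp_path / "c.tsv"
    write_centroids(panel, path)
    back = read_centroids(path)
    pd.testing.assert_frame_equal(back.centroids, panel.centroids, check_names=False)
    single = _write(tmp_path / "one.tsv", "gene_id\tLumA\nAURKA\t1.0\nESR1\t2.0\n")
    with pytest.raises(FormatError, match="2 subtypes"):
        read_centroids(single)
    with pytest.raises(FormatError):
        GeneSetCollection({"empty": []})


def test_expression_matrix_rejects_duplicate_ids():
    df = pd.DataFrame([[1.0], [2.0]], index=["g", "g"], columns=["s"])
    with pytest.raises(FormatError):
        ExpressionMatrix(df)
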