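"""Matrix reading/writing, VCF ingestion and homoplasy filtering."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from truncal import (
    AlterationMatrix,
    MatrixFormatError,
    filter_homoplasy,
    find_conflicts,
    read_matrix,
    vcf_to_matrix,
    write_matrix,
)

from conftest import brute_force_conflicts


def _matrix_from_rows(rows: dict[str, list[int]], samples: list[str]) -> AlterationMatrix:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    frame.index.name = "alteration_id"
    return AlterationMatrix(frame)


# ---------------------------------------------------------------- round trip


def test_round_trip_tsv_and_csv(worked_matrix):
    for dialect in ("tsv", "csv"):
        buf = io.StringIO()
        write_matrix(worked_matrix, buf, dialect=dialect)
        buf.seek(0)
        again = read_matrix(buf, dialect=dialect)
        assert again == worked_matrix


def test_round_trip_single_sample_and_unicode_names():
    m = _matrix_from_rows({"mut-α": [1], "mut-β": [1]}, ["пример"])
    buf = io.StringIO()
    write_matrix(m, buf)
    buf.seek(0)
    again = read_matrix(buf)
    assert again.sample_ids == ["пример"]
    assert again.alteration_ids == ["mut-α", "mut-β"]


@given(
    st.integers(min_value=1, max_value=6),
    st.integers(min_value=1, max_value=10),
    st.randoms(use_true_random=False),
)
@settings(derandomize=True, max_examples=25, deadline=None)
def test_round_trip_random_matrices(n_samples, n_alts, rnd):
    rows = {}
    for r in range(n_alts):
        vals = [rnd.randint(0, 1) for _ in range(n_samples)]
        if sum(vals) == 0:
            vals[rnd.randrange(n_samples)] = 1
        rows[f"a{r}"] = vals
    m = _matrix_from_rows(rows, [f"s{j}" for j in range(n_samples)])
    buf = io.StringIO()
    write_matrix(m, buf)
    buf.seek(0)
    assert read_matrix(buf) == m


# ---------------------------------------------------------------- validation


def test_non_binary_cell_names_row_and_column():
    text = "alteration_id\ts1\ts2\nA\t1\t2\n"
    with pytest.raises(MatrixFormatError, match="'2'.*'A'.*'s2'"):
        read_matrix(io.StringIO(text))


def test_duplicate_identifiers_rejected():
    text = "alteration_id\ts1\ts1\nA\t1\t0\n"
    with pytest.raises(MatrixFormatError, match="duplicate sample"):
        read_matrix(io.StringIO(text))
    text = "alteration_id\ts1\nA\t1\nA\t1\n"
    with pytest.raises(MatrixFormatError, match="duplicate alteration"):
        read_matrix(io.StringIO(text))


def test_all_zero_alteration_dropped_with_warning():
    text = "alteration_id\ts1\ts2\nA\t1\t0\nB\t0\t0\n"
    with pytest.warns(UserWarning, match="absent from every sample"):
        m = read_matrix(io.StringIO(text))
    assert m.alteration_ids == ["A"]


def test_wrong_orientation_rejected():
    text = "sample_id\tA\tB\ns1\t1\t0\n"
    with pytest.raises(MatrixFormatError, match="transposed"):
        read_matrix(io.StringIO(text))


def test_empty_matrix_rejected():
    with pytest.raises((MatrixFormatError, pd.errors.EmptyDataError)):
        read_matrix(io.StringIO("alteration_id\ts1\n"))


# --------------------------------------------------------------- VCF on-ramp

TOY_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
    chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/0
    chr1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t1/2\t0/0
    chr1\t300\t.\tT\tC\t.\tPASS\t.\tGT\t./.\t1/1
    """
)


def _write_vcf(tmp_path, text=TOY_VCF):
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


def test_vcf_presence_calls(tmp_path):
    path = _write_vcf(tmp_path)
    with pytest.warns(UserWarning, match="missing genotypes"):
        m = vcf_to_matrix(path, missing_policy="absent")
    assert m.sample_ids == ["A", "B"]
    assert m.data.loc["chr1:100:G:A"].tolist() == [1, 0]
    assert m.data.loc["chr1:200:C:T,G"].tolist() == [1, 0]  # any alternate allele
    assert m.data.loc["chr1:300:T:C"].tolist() == [0, 1]  # ./. scored absent


def test_vcf_drop_site_policy(tmp_path):
    path = _write_vcf(tmp_path)
    m = vcf_to_matrix(path, missing_policy="drop_site")
    assert "chr1:300:T:C" not in m.alteration_ids
    assert m.n_alterations == 2


def test_vcf_without_genotypes_rejected(tmp_path):
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=1000000>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        chr1\t100\t.\tG\tA\t.\tPASS\t.
        """
    )
    path = tmp_path / "nogt.vcf"
    path.write_text(text)
    with pytest.raises(MatrixFormatError, match="no sample columns"):
        vcf_to_matrix(path)


def test_vcf_zero_retained_records_rejected(tmp_path):
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=1000000>
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
        chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/1
        """
    )
    path = tmp_path / "allmiss.vcf"
    path.write_text(text)
    with pytest.raises(MatrixFormatError, match="no VCF records retained"):
        vcf_to_matrix(path, missing_policy="drop_site")


# ------------------------------------------------------- three-gamete test


@pytest.mark.parametrize(
    ("a", "b", "conflict"),
    [
        ([1, 1, 0, 0], [0, 0, 1, 1], False),  # disjoint: (1,1) absent
        ([1, 1, 1], [1, 1, 0], False),  # nested
        ([1, 1, 0], [1, 0, 1], True),  # all three patterns
    ],
)
def test_pairwise_conflict_examples(a, b, conflict):
    m = _matrix_from_rows({"a": a, "b": b}, [f"s{j}" for j in range(len(a))])
    report = find_conflicts(m)
    assert (("a", "b") in report.conflicting_pairs) == conflict
    assert report.is_compatible != conflict


def test_find_conflicts_agrees_with_pattern_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        rows = {}
        for r in range(8):
            vals = rng.integers(0, 2, size=5)
            if vals.sum() == 0:
                vals[rng.integers(5)] = 1
            rows[f"a{r}"] = vals.tolist()
        m = _matrix_from_rows(rows, [f"s{j}" for j in range(5)])
        assert set(find_conflicts(m).conflicting_pairs) == brute_force_conflicts(m)


def test_filter_removes_most_conflicted_alteration():
    # c conflicts with both a and b (verified by pattern enumeration);
    # a and b are mutually nested, one conflict each -> greedy removes c only
    m = _matrix_from_rows(
        {"a": [1, 1, 0, 0], "b": [1, 1, 1, 0], "c": [1, 0, 1, 1]},
        ["s1", "s2", "s3", "s4"],
    )
    assert brute_force_conflicts(m) == {("a", "c"), ("b", "c")}
    filtered, removed = filter_homoplasy(m)
    assert removed == ["c"]
    assert filtered.alteration_ids == ["a", "b"]
    assert find_conflicts(filtered).is_compatible


def test_filter_noop_on_compatible_matrices(worked_matrix):
    filtered, removed = filter_homoplasy(worked_matrix)
    assert removed == []
    assert filtered == worked_matrix
    nested = _matrix_from_rows(
        {"a": [1, 1, 1], "b": [1, 1, 0], "c": [1, 0, 0]}, ["s1", "s2", "s3"]
    )
    assert filter_homoplasy(nested)[0] == nested


def test_filter_is_idempotent_and_output_compatible():
    rng = np.random.default_rng(5)
    for _ in range(10):
        rows = {f"a{r}": rng.integers(0, 2, size=6).tolist() for r in range(10)}
        rows = {k: v if sum(v) else [1] + v[1:] for k, v in rows.items()}
        m = _matrix_from_rows(rows, [f"s{j}" for j in range(6)])
        once, removed_once = filter_homoplasy(m)
        assert find_conflicts(once).is_compatible
        twice, removed_twice = filter_homoplasy(once)
        assert removed_twice == []
        assert twice == once


def test_conflict_report_json(worked_matrix):
    report = find_conflicts(worked_matrix)
    assert report.to_json(removed=[]) == '{"conflicting_pairs": [], "removed": []}'
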