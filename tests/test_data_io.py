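"""Genotype/annotation IO, HWE and QC filters, SNP-to-gene assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genemdr import data_io
from genemdr.data_io import (
    EmptyMatrixError,
    GenotypeParseError,
    GenotypeMatrix,
    QCThresholds,
    apply_qc,
    assign_snps_to_genes,
    hwe_test,
    read_genotypes,
    write_genotypes,
)

from conftest import random_genotype_matrix


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

TSV_2x2 = (
    "sample_id\tphenotype\trs1\trs2\n"
    "A\t1\t0\t1\n"
    "B\t0\t2\t0\n"
)


def test_tsv_identity_read_back(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(TSV_2x2)
    g = read_genotypes(path, format="tsv")
    assert g.samples == ["A", "B"]
    assert g.snp_ids == ["rs1", "rs2"]
    np.testing.assert_array_equal(g.calls, [[0, 1], [2, 0]])
    np.testing.assert_array_equal(g.phenotype, [1, 0])


def test_tsv_round_trip(tmp_path, rng):
    g = random_genotype_matrix(rng, 15, 7)
    path = tmp_path / "g.tsv"
    write_genotypes(g, path)
    g2 = read_genotypes(path, format="tsv")
    assert g2.samples == g.samples and g2.snp_ids == g.snp_ids
    np.testing.assert_array_equal(g2.calls, g.calls)
    np.testing.assert_array_equal(g2.phenotype, g.phenotype)
    # and a second write is byte-identical
    path2 = tmp_path / "g2.tsv"
    write_genotypes(g2, path2)
    assert path.read_bytes() == path2.read_bytes()


@pytest.mark.parametrize(
    "content, match",
    [
        ("sample_id\tphenotype\trs1\nA\t1\tNA\n", "impute"),
        ("sample_id\tphenotype\trs1\nA\t1\t3\n", "0/1/2"),
        ("sample_id\tphenotype\trs1\trs1\nA\t1\t0\t0\n", "duplicate"),
        ("sample_id\tphenotype\trs1\nA\t2\t0\n", "phenotype"),
        ("sample_id\trs1\nA\t0\n", "header"),
    ],
)
def test_tsv_parse_errors(tmp_path, content, match):
    path = tmp_path / "bad.tsv"
    path.write_text(content)
    with pytest.raises((GenotypeParseError, ValueError), match=match):
        read_genotypes(path, format="tsv")


def test_tsv_error_names_line_and_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample_id\tphenotype\trs1\trs2\nA\t1\t0\t1\nB\t0\t0\tx\n")
    with pytest.raises(GenotypeParseError, match=r":3: column 4"):
        read_genotypes(path, format="tsv")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def test_plink_minor_allele_counting(tmp_path):
    # allele tally over the file: A appears 1x, G 3x -> minor allele is A
    (tmp_path / "d.map").write_text("1 rs1 0 1000\n")
    (tmp_path / "d.ped").write_text(
        "FAM1 IND1 0 0 1 2 A G\n"
        "FAM1 IND2 0 0 2 1 G G\n"
    )
    g = read_genotypes(tmp_path / "d.ped", format="plink-text")
    assert g.samples == ["FAM1:IND1", "FAM1:IND2"]
    np.testing.assert_array_equal(g.calls[:, 0], [1, 0])  # minor-allele counts
    np.testing.assert_array_equal(g.phenotype, [1, 0])  # 2=case, 1=control
    assert g.chrom == ["1"] and g.pos[0] == 1000


def test_plink_missing_tolerated_then_filtered(tmp_path):
    (tmp_path / "d.map").write_text("1 rs1 0 1000\n1 rs2 0 2000\n")
    ped = "".join(
        f"F I{i} 0 0 1 {1 + i % 2} {'0 0' if i < 3 else 'A G'} A A\n"
        for i in range(10)
    )
    (tmp_path / "d.ped").write_text(ped)
    g = read_genotypes(tmp_path / "d.ped", format="plink-text")
    assert (g.calls[:3, 0] == data_io.MISSING).all()
    g2, report = apply_qc(g, QCThresholds(maf_min=0.0, missing_max=0.05))
    assert "rs1" not in g2.snp_ids  # 30% missing > 5%
    row = report.set_index("snp_id").loc["rs1"]
    assert row["removed"] and "missingness" in row["reasons"]


def test_plink_non_biallelic_rejected(tmp_path):
    (tmp_path / "d.map").write_text("1 rs1 0 1000\n")
    (tmp_path / "d.ped").write_text("F I1 0 0 1 2 A G\nF I2 0 0 1 1 C C\n")
    with pytest.raises(GenotypeParseError, match="2 alleles"):
        read_genotypes(tmp_path / "d.ped", format="plink-text")


# ---------------------------------------------------------------------------
# HWE
# ---------------------------------------------------------------------------

def test_hwe_exact_proportions():
    res = hwe_test((25, 50, 25))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert not res.monomorphic


def test_hwe_extreme_departure():
    # expected (25, 50, 25); chi-square = 25 + 50 + 25 = n = 100
    res = hwe_test((50, 0, 50))
    assert res.statistic == pytest.approx(100.0)
    assert res.p_value < 1e-20


def test_hwe_monomorphic():
    res = hwe_test((100, 0, 0))
    assert res.p_value == 1.0 and res.monomorphic


@settings(max_examples=200, deadline=None)
@given(
    n0=st.integers(0, 500), n1=st.integers(0, 500), n2=st.integers(0, 500)
)
def test_hwe_matches_hand_computed_chi2_tail(n0, n1, n2):
    if n0 + n1 + n2 == 0:
        return
    res = hwe_test((n0, n1, n2))
    assert 0.0 <= res.p_value <= 1.0
    n = n0 + n1 + n2
    q = (n1 + 2 * n2) / (2 * n)
    if q in (0.0, 1.0):
        assert res.monomorphic
        return
    exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2]
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
    assert res.statistic == pytest.approx(chi2)
    assert res.p_value == pytest.approx(float(stats.chi2.sf(chi2, 1)))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _matrix_from_columns(columns, phenotype):
    calls = np.column_stack(columns).astype(np.int8)
    n, p = calls.shape
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(p)],
        chrom=["1"] * p,
        pos=np.arange(1, p + 1) * 100,
        calls=calls,
        phenotype=np.asarray(phenotype, dtype=np.int8),
    )


def test_qc_low_maf_removed():
    n = 100
    rare = np.zeros(n, dtype=int)
    rare[:8] = 1  # MAF 0.04 < 0.05
    common = np.tile([0, 1, 2, 1], 25)
    phen = np.repeat([0, 1], 50)  # controls see the 0/1/2/1 cycle: ~HWE at MAF 0.5
    g = _matrix_from_columns([rare, common], phen)
    g2, report = apply_qc(g)
    assert g2.snp_ids == ["snp1"]
    row = report.set_index("snp_id").loc["snp0"]
    assert row["maf"] == pytest.approx(0.04)
    assert row["removed"] and "MAF < 0.05" in row["reasons"]


def test_qc_hwe_pass_retained():
    # control genotype counts (25, 50, 25): perfect HWE, MAF 0.5
    ctrl = np.repeat([0, 1, 2], [25, 50, 25])
    case = np.repeat([0, 1, 2], [25, 50, 25])
    col = np.concatenate([ctrl, case])
    phen = np.repeat([0, 1], 100)
    g = _matrix_from_columns([col], phen)
    g2, report = apply_qc(g)
    assert g2.snp_ids == ["snp0"]
    assert not report["removed"].any()


def test_qc_hwe_failure_in_controls_removed():
    ctrl = np.repeat([0, 2], [50, 50])  # no hets: chi2 = 100, p << 5.7e-7
    case = np.repeat([0, 1, 2], [25, 50, 25])
    good = np.tile([0, 1, 2, 1], 50)
    phen = np.repeat([0, 1], 100)
    g = _matrix_from_columns([np.concatenate([ctrl, case]), good], phen)
    g2, report = apply_qc(g)
    assert g2.snp_ids == ["snp1"]
    assert "HWE" in report.set_index("snp_id").loc["snp0", "reasons"]


def test_qc_survivor_count_and_idempotence(rng):
    n = 200
    phen = np.tile([0, 1], 100)
    cols = [rng.binomial(2, 0.3, size=n) for _ in range(3)]
    for maf in (0.02, 0.03):  # exactly 2 SNPs fail MAF
        c = np.zeros(n, dtype=int)
        c[: int(round(2 * maf * n))] = 1
        cols.append(c)
    g = _matrix_from_columns(cols, phen)
    g2, report = apply_qc(g)
    assert g2.n_snps == 3
    assert int(report["removed"].sum()) == 2
    g3, report2 = apply_qc(g2)
    assert g3.snp_ids == g2.snp_ids
    np.testing.assert_array_equal(g3.calls, g2.calls)
    assert not report2["removed"].any()


def test_qc_all_removed_is_error():
    n = 100
    rare = np.zeros(n, dtype=int)
    rare[:2] = 1
    g = _matrix_from_columns([rare], np.tile([0, 1], 50))
    with pytest.raises(EmptyMatrixError, match="every SNP"):
        apply_qc(g)


# ---------------------------------------------------------------------------
# SNP -> gene assignment
# ---------------------------------------------------------------------------

def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"])


def _snps(positions, chroms=None):
    p = len(positions)
    chroms = chroms or ["chr1"] * p
    return GenotypeMatrix(
        samples=["A", "B"],
        snp_ids=[f"snp{j}" for j in range(p)],
        chrom=chroms,
        pos=np.asarray(positions),
        calls=np.zeros((2, p), dtype=np.int8),
        phenotype=np.array([1, 0], dtype=np.int8),
    )


def test_assignment_inside_gene():
    genes = _genes([("chr1", 999, 10_000, "A")])  # BED for 1-based 1000..10000
    gm = assign_snps_to_genes(_snps([5000]), genes)
    assert gm.assignments == {"snp0": "A"}
    assert gm.unassigned == []


def test_beyond_window_unassigned():
    genes = _genes([("chr1", 300_000, 350_000, "A")])
    gm = assign_snps_to_genes(_snps([500_000]), genes, window=100_000)
    assert gm.assignments == {}
    assert gm.unassigned == ["snp0"]  # 150 kb away > 100 kb


def test_equidistant_tie_goes_to_lexicographically_first():
    # SNP at 1-based 100,000 -> 0-based 99,999; both genes 30 kb away
    genes = _genes(
        [
            ("chr1", 129_999, 140_000, "B"),  # start - z = 30,000
            ("chr1", 129_999, 140_000, "A"),
            ("chr1", 40_000, 70_000, "C"),  # z - (end-1) = 30,000
        ]
    )
    gm = assign_snps_to_genes(_snps([100_000]), genes, window=100_000)
    assert gm.assignments["snp0"] == "A"


def test_gene_line_order_invariance(rng):
    rows = [
        ("chr1", int(s), int(s) + 20_000, f"G{i:02d}")
        for i, s in enumerate(rng.integers(0, 2_000_000, size=15))
    ]
    g = _snps(list(rng.integers(1, 2_100_000, size=30)))
    base = assign_snps_to_genes(g, _genes(rows))
    perm = [rows[i] for i in rng.permutation(len(rows))]
    shuffled = assign_snps_to_genes(g, _genes(perm))
    assert base.assignments == shuffled.assignments
    assert base.unassigned == shuffled.unassigned


def test_assignment_distance_within_window(rng):
    rows = [
        ("chr1", int(s), int(s) + 10_000, f"G{i:02d}")
        for i, s in enumerate(rng.integers(0, 3_000_000, size=20))
    ]
    genes = _genes(rows)
    g = _snps(list(rng.integers(1, 3_100_000, size=50)))
    window = 50_000
    gm = assign_snps_to_genes(g, genes, window=window)
    assert set(gm.assignments) | set(gm.unassigned) == set(g.snp_ids)
    lookup = genes.set_index("symbol")
    for sid, sym in gm.assignments.items():
        z = int(g.pos[g.snp_ids.index(sid)]) - 1
        start, end = lookup.loc[sym, "start"], lookup.loc[sym, "end"]
        dist = max(start - z, z - (end - 1), 0)
        assert dist <= window


def test_chromosome_mismatch_warns_and_unassigns():
    genes = _genes([("chr1", 0, 10_000, "A")])
    g = _snps([5000, 5000], chroms=["chr1", "chrX"])
    with pytest.warns(UserWarning, match="chrX"):
        gm = assign_snps_to_genes(g, genes)
    assert gm.assignments == {"snp0": "A"}
    assert gm.unassigned == ["snp1"]
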