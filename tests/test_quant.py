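"""TPM/RPKM normalization, the expression filter and Spearman QC."""

import numpy as np
import pandas as pd
import pytest

from homeobias.quant import (
    ExpressionTable,
    compute_rpkm,
    compute_tpm,
    filter_expressed,
    read_counts,
    read_lengths,
    read_metadata,
    sample_correlation,
    validate_metadata,
)


def _table(values, lengths, sample_ids=None, library_sizes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    tids = [f"t{i}" for i in range(values.shape[0])]
    sids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionTable(
        values=pd.DataFrame(values, index=tids, columns=sids),
        unit="count",
        lengths=pd.Series(lengths, index=tids, dtype=float),
        library_sizes=(
            pd.Series(library_sizes, index=sids, dtype=float)
            if library_sizes is not None
            else None
        ),
    )


class TestTPM:
    def test_single_transcript_forced_to_million(self):
        tpm = compute_tpm(_table([[17.0]], [812]))
        assert tpm.values.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_length_normalized_rates(self):
        # counts (10, 20) at lengths (1000, 2000): identical rates
        tpm = compute_tpm(_table([[10.0], [20.0]], [1000, 2000]))
        assert tpm.values["s0"].tolist() == pytest.approx([5e5, 5e5])

    def test_all_zero_sample_warns_and_stays_zero(self):
        tbl = _table([[5.0, 0.0], [3.0, 0.0]], [100, 200])
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(tbl)
        assert (tpm.values["s1"] == 0).all()
        assert tpm.values["s0"].sum() == pytest.approx(1e6)

    @pytest.mark.parametrize("seed", range(3))
    def test_columns_sum_to_million(self, seed):
        rng = np.random.default_rng(seed)
        tbl = _table(rng.poisson(50, (40, 6)), rng.integers(200, 5000, 40))
        tpm = compute_tpm(tbl)
        assert tpm.unit == "TPM"
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_rejects_wrong_unit(self):
        tbl = _table([[1.0]], [100])
        tbl.unit = "TPM"
        with pytest.raises(ValueError, match="unit"):
            compute_tpm(tbl)


class TestRPKM:
    def test_definition_anchor(self):
        # 10 reads, 1 kb transcript, 1e6 mapped reads -> RPKM 10
        r = compute_rpkm(_table([[10.0]], [1000], library_sizes=[1e6]))
        assert r.values.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        r = compute_rpkm(_table([[0.0]], [1000], library_sizes=[1e6]))
        assert r.values.iloc[0, 0] == 0.0

    def test_direct_arithmetic(self):
        r = compute_rpkm(_table([[7.0]], [1500], library_sizes=[2.5e6]))
        assert r.values.iloc[0, 0] == pytest.approx(7 * 1e9 / (1500 * 2.5e6))

    def test_library_size_defaults_to_column_sums(self):
        tbl = _table([[30.0], [70.0]], [1000, 1000])
        r = compute_rpkm(tbl)
        assert r.values.iloc[0, 0] == pytest.approx(30 * 1e9 / (1000 * 100))

    @pytest.mark.parametrize("seed", range(3))
    def test_linearity_and_inverse_scaling(self, seed):
        rng = np.random.default_rng(10 + seed)
        counts = rng.poisson(100, (20, 4)).astype(float)
        lengths = rng.integers(500, 3000, 20)
        libs = rng.integers(int(1e5), int(1e6), 4).astype(float)
        base = compute_rpkm(_table(counts, lengths, library_sizes=libs)).values
        doubled = compute_rpkm(
            _table(2 * counts, lengths, library_sizes=libs)
        ).values
        np.testing.assert_allclose(doubled, 2 * base)
        half_len = compute_rpkm(
            _table(counts, lengths * 2, library_sizes=libs)
        ).values
        np.testing.assert_allclose(half_len, base / 2)
        big_lib = compute_rpkm(
            _table(counts, lengths, library_sizes=libs * 4)
        ).values
        np.testing.assert_allclose(big_lib, base / 4)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError, match="library size"):
            compute_rpkm(_table([[1.0]], [100], library_sizes=[0.0]))


class TestFilterExpressed:
    def test_boundary_inclusive(self):
        tbl = _table([[0.5, 0.9, 0.99], [0.0, 0.0, 1.0]], [100, 100])
        tbl.unit = "TPM"
        assert filter_expressed(tbl) == {"t1"}

    def test_zero_threshold_keeps_all(self):
        tbl = _table([[0.0, 0.0], [0.2, 0.0]], [100, 100])
        tbl.unit = "TPM"
        assert filter_expressed(tbl, min_tpm=0.0) == {"t0", "t1"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        tbl = _table(rng.exponential(2.0, (50, 5)), rng.integers(100, 500, 50))
        tbl.unit = "TPM"
        kept = [filter_expressed(tbl, min_tpm=t) for t in (0.5, 1.0, 2.0, 5.0)]
        for loose, strict in zip(kept, kept[1:]):
            assert strict <= loose


class TestSampleCorrelation:
    def test_duplicated_sample_is_one(self):
        x = np.arange(6, dtype=float)
        tbl = _table(np.column_stack([x, x, x[::-1]]), [100] * 6)
        rho = sample_correlation(tbl)
        assert rho.loc["s0", "s1"] == pytest.approx(1.0)
        assert np.allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho.values, rho.values.T)

    def test_monotone_reversal_is_minus_one(self):
        tbl = _table(np.column_stack([[1, 2, 3], [9, 4, 2]]), [100] * 3)
        rho = sample_correlation(tbl)
        assert rho.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        # 5-transcript toy with ties, against rank-then-Pearson by hand
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        b = np.array([5.0, 5.0, 7.0, 8.0, 9.0])
        ranks_a = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ranks_b = np.array([1.5, 1.5, 3.0, 4.0, 5.0])
        expected = np.corrcoef(ranks_a, ranks_b)[0, 1]
        tbl = _table(np.column_stack([a, b]), [100] * 5)
        assert sample_correlation(tbl).loc["s0", "s1"] == pytest.approx(expected)

    def test_constant_sample_missing_with_warning(self):
        tbl = _table(np.column_stack([[1, 2, 3], [4, 4, 4]]), [100] * 3)
        with pytest.warns(UserWarning, match="constant"):
            rho = sample_correlation(tbl)
        assert np.isnan(rho.loc["s0", "s1"])
        assert rho.loc["s1", "s1"] == 1.0


class TestReadersAndMetadata:
    def test_counts_lengths_round_trip(self, tmp_path):
        counts = pd.DataFrame(
            [[3, 0], [1, 9]], index=["tA", "tB"], columns=["s1", "s2"]
        )
        cpath = tmp_path / "c.tsv"
        counts.rename_axis("transcript_id").to_csv(cpath, sep="\t")
        lpath = tmp_path / "l.tsv"
        lpath.write_text("transcript_id\tlength\ntA\t100\ntB\t250\n")
        tbl = read_counts(cpath, lengths=read_lengths(lpath))
        assert tbl.values.values.tolist() == [[3.0, 0.0], [1.0, 9.0]]
        assert tbl.lengths.tolist() == [100, 250]

    def test_lengths_from_fasta(self, tmp_path):
        fpath = tmp_path / "seqs.fa"
        fpath.write_text(">tA desc\nACGTACGT\n>tB\nACGTACGTAC\nGT\n")
        lengths = read_lengths(fpath)
        assert lengths["tA"] == 8
        assert lengths["tB"] == 12

    def test_metadata_validation(self, tmp_path):
        good = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "taxon": ["P1", "F1"],
                "condition": ["30C", "30C"],
                "replicate": [1, 1],
            }
        )
        validate_metadata(good)
        bad_taxon = good.assign(taxon=["P1", "XX"])
        with pytest.raises(ValueError, match="taxon"):
            validate_metadata(bad_taxon)
        dup = pd.concat([good, good])
        with pytest.raises(ValueError, match="duplicate"):
            validate_metadata(dup)
        mpath = tmp_path / "meta.tsv"
        good.to_csv(mpath, sep="\t", index=False)
        assert read_metadata(mpath)["taxon"].tolist() == ["P1", "F1"]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _table([[-1.0]], [100])
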