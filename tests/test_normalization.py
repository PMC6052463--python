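"""Filtering, TMM factors (against a brute-force oracle), log-RPKM, and
standardization."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longsig.normalization import (CountMatrix, ExpressionMatrix,
                                   filter_low_expression, normalcy_fraction,
                                   read_counts_tsv, standardize, tmm_factors,
                                   to_log_rpkm, write_counts_tsv)


def make_counts(arr, species=None, lengths=None):
    arr = np.asarray(arr)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    species = species or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=species)
    lg = pd.Series(lengths if lengths is not None else 1000, index=genes)
    return CountMatrix(counts=df, gene_length_bp=lg)


class TestFilter:
    @pytest.mark.parametrize("row,kept", [
        ([0, 0, 0, 9, 9], False),    # 3 species below 3 -> removed
        ([3, 3, 3, 0, 0], True),     # only 2 below 3 -> retained
        ([3, 3, 3, 3, 3], True),
        ([2, 2, 2, 2, 2], False),
    ])
    def test_low_expression_rule(self, row, kept):
        m = make_counts([row, [10] * 5])
        out = filter_low_expression(m)
        assert ("g0" in out.gene_ids) is kept
        assert "g1" in out.gene_ids

    def test_identity_when_all_expressed(self):
        m = make_counts(np.full((4, 5), 7))
        out = filter_low_expression(m)
        assert out.gene_ids == m.gene_ids

    def test_empty_result_warns(self):
        m = make_counts(np.full((2, 5), 2))
        with pytest.warns(UserWarning):
            out = filter_low_expression(m)
        assert len(out.gene_ids) == 0


def oracle_tmm_factor(obs, ref, lib_obs, lib_ref, trim_m=0.30, trim_a=0.05):
    """Independent brute-force doubly-trimmed weighted mean of M-values
    (pure-Python sort-based ranks)."""
    rows = []
    for x, r in zip(obs, ref):
        if x > 0 and r > 0:
            o, q = x / lib_obs, r / lib_ref
            M = math.log2(o / q)
            A = 0.5 * math.log2(o * q)
            var = (lib_obs - x) / (lib_obs * x) + (lib_ref - r) / (lib_ref * r)
            rows.append((M, A, var))
    n = len(rows)
    if n == 0:
        raise ValueError("no shared expressed genes")
    if max(abs(m) for m, _, _ in rows) < 1e-6:
        return 1.0

    def ranks(vals):
        order = sorted(range(n), key=lambda i: vals[i])
        rk = [0.0] * n
        i = 0
        while i < n:
            j = i
            while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                rk[order[k]] = avg
            i = j + 1
        return rk

    rm = ranks([m for m, _, _ in rows])
    ra = ranks([a for _, a, _ in rows])
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for (M, A, var), km, ka in zip(rows, rm, ra):
        if lo_m <= km <= hi_m and lo_a <= ka <= hi_a:
            num += M / var
            den += 1.0 / var
    if den == 0:
        return 1.0
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        arr = np.tile([[10], [50], [200], [5]], (1, 3))
        f = tmm_factors(make_counts(arr))
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        base = np.array([[10, 50, 200, 5, 80, 33]]).T
        arr = np.hstack([base, 4 * base])
        f = tmm_factors(make_counts(arr))
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_worked_matrix_matches_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson([20, 80, 300, 15, 60, 500], size=(6, 6)).T * \
            np.array([1, 1, 1, 1, 1, 1])
        arr = np.maximum(arr, 1)
        m = make_counts(arr)
        ref = m.species_ids[0]
        f = tmm_factors(m, ref=ref)
        lib = m.library_size.to_numpy()
        raw = np.ones(len(f))
        for k in range(1, arr.shape[1]):
            raw[k] = oracle_tmm_factor(arr[:, k], arr[:, 0], lib[k], lib[0])
        raw /= np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), raw, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_oracle_on_random_fixtures(self, seed):
        """Property: factors equal the brute-force trimmed-weighted-mean
        oracle on random 10-gene matrices."""
        rng = np.random.default_rng(seed)
        arr = rng.integers(1, 1000, size=(10, 4))
        m = make_counts(arr)
        ref = m.species_ids[0]
        f = tmm_factors(m, ref=ref).to_numpy()
        lib = m.library_size.to_numpy()
        raw = np.ones(4)
        for k in range(1, 4):
            raw[k] = oracle_tmm_factor(arr[:, k], arr[:, 0], lib[k], lib[0])
        raw /= np.exp(np.mean(np.log(raw)))
        assert np.allclose(f, raw, atol=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(1, 500, size=(40, 5))
        f = tmm_factors(make_counts(arr))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_library_rejected(self):
        arr = np.array([[5, 0], [7, 0]])
        with pytest.raises(ValueError):
            tmm_factors(make_counts(arr))

    def test_matches_edger_reference(self):
        """Cross-check against Bioconductor edgeR's calcNormFactors on a
        composition-biased matrix (skipped when Rscript/edgeR missing)."""
        import shutil
        import subprocess
        import tempfile
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        mu = rng.lognormal(4, 1.5, size=200)
        libs = np.array([1.0, 2.0, 0.7, 1.5])
        arr = rng.poisson(mu[:, None] * libs[None, :])
        arr[:10, 0] *= 8
        arr = np.maximum(arr, 0)
        with tempfile.NamedTemporaryFile("w", suffix=".tsv") as fh:
            np.savetxt(fh.name, arr, fmt="%d", delimiter="\t")
            script = (
                'suppressMessages(library(edgeR));'
                f'x <- as.matrix(read.table("{fh.name}"));'
                'cat(calcNormFactors(x, method="TMM"), sep="\\n")')
            try:
                res = subprocess.run(["Rscript", "-e", script], timeout=120,
                                     capture_output=True, text=True)
            except subprocess.TimeoutExpired:
                pytest.skip("Rscript timed out")
            if res.returncode != 0:
                pytest.skip("edgeR not available")
            expected = np.array([float(v) for v in res.stdout.split()])
        f = tmm_factors(make_counts(arr))
        assert np.allclose(f.to_numpy(), expected, atol=1e-6)


class TestLogRPKM:
    def test_unit_arithmetic(self):
        m = make_counts([[10]], lengths=[1000])
        m.library_size[:] = 10 ** 6
        e = to_log_rpkm(m)
        assert e.values.iloc[0, 0] == pytest.approx(np.log(10), abs=1e-12)

    def test_zero_count_handling(self):
        m = make_counts([[0, 5], [9, 9]], lengths=[1000, 1000])
        with pytest.warns(UserWarning):
            e = to_log_rpkm(m)
        assert np.isneginf(e.values.iloc[0, 0])
        e2 = to_log_rpkm(m, pseudocount=1e-3)
        assert np.isfinite(e2.values.iloc[0, 0])

    def test_scale_invariance(self):
        arr = np.array([[10, 30], [70, 20]])
        m1 = make_counts(arr)
        m2 = make_counts(2 * arr)
        e1 = to_log_rpkm(m1)
        e2 = to_log_rpkm(m2)
        assert np.allclose(e1.values, e2.values)


class TestStandardize:
    def test_three_point_row(self):
        e = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                                          columns=list("abc")))
        z = standardize(e)
        assert np.allclose(z.values, [[-1, 0, 1]])

    def test_idempotent(self, rng):
        e = ExpressionMatrix(pd.DataFrame(rng.standard_normal((20, 6)),
                                          index=[f"g{i}" for i in range(20)],
                                          columns=list("abcdef")))
        z1 = standardize(e)
        z2 = standardize(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_row_moments(self, rng):
        e = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((100, 14)) * 3 + 5,
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(14)]))
        z = standardize(e)
        assert np.abs(z.values.mean(axis=1)).max() < 1e-12
        assert np.abs(z.values.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_constant_rows_dropped(self):
        e = ExpressionMatrix(pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]],
                                          index=["flat", "ok"],
                                          columns=list("abc")))
        with pytest.warns(UserWarning):
            z = standardize(e)
        assert z.gene_ids == ["ok"]


class TestNormalcy:
    def test_gaussian_rows_near_nominal_level(self):
        rng = np.random.default_rng(13)
        e = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((1000, 14)),
            index=[f"g{i}" for i in range(1000)],
            columns=[f"s{j}" for j in range(14)]))
        frac = normalcy_fraction(e, alpha=0.05)
        assert frac == pytest.approx(0.95, abs=0.03)

    def test_heavy_tailed_rows_flagged(self):
        rng = np.random.default_rng(14)
        normal = normalcy_fraction(ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((300, 14)))), alpha=0.05)
        heavy = normalcy_fraction(ExpressionMatrix(pd.DataFrame(
            rng.standard_t(df=1, size=(300, 14)))), alpha=0.05)
        assert heavy < normal - 0.2


class TestPipelineRecovery:
    def test_counts_round_trip_recovers_standardized_expression(self, tree14):
        """filter -> tmm -> log-RPKM -> standardize on synthetic counts
        recovers the generating standardized expression (r > 0.95 per gene
        at deep libraries)."""
        from longsig.synthetic import (SimConfig, expression_to_counts,
                                       generate_expression, generate_traits)
        cfg = SimConfig(n_genes=200, signature_fraction=0.1)
        tr = generate_traits(tree14, cfg, seed=20)
        std, lr, _ = generate_expression(tree14, tr, cfg, seed=21)
        rng = np.random.default_rng(22)
        lengths = rng.integers(500, 5000, size=200)
        libs = np.full(14, 10 ** 7)
        m = expression_to_counts(lr, lengths, libs, seed=23)
        m = filter_low_expression(m)
        f = tmm_factors(m)
        z = standardize(to_log_rpkm(m, f, pseudocount=0.5))
        common = z.values.index
        corr = [np.corrcoef(z.values.loc[g], std.values.loc[g])[0, 1]
                for g in common]
        assert np.median(corr) > 0.95


def test_counts_tsv_round_trip(tmp_path):
    m = make_counts([[3, 5, 2], [10, 0, 7]], lengths=[900, 2500])
    write_counts_tsv(m, tmp_path / "c.tsv")
    back = read_counts_tsv(tmp_path / "c.tsv")
    pd.testing.assert_frame_equal(back.counts, m.counts, check_names=False)
    assert (back.gene_length_bp.to_numpy() == m.gene_length_bp.to_numpy()).all()
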