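"""Codon fold-difference, Z selection, context extraction and logo statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from riboshift import io as rio
from riboshift import stalling as st


def _codon_table(counts_per_gene):
    frames = []
    for tx, counts in counts_per_gene.items():
        counts = np.asarray(counts, float)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tx,
                    "codon_index": np.arange(counts.size),
                    "count": counts,
                    "rpm": counts,
                }
            )
        )
    return pd.concat(frames).set_index(["transcript_id", "codon_index"])


class TestDensityNormalisation:
    def test_within_gene_mean_normalisation(self):
        """Counts [2,2,4] have mean 8/3: normalised [0.75, 0.75, 1.5]."""
        norm = st.codon_density_table(_codon_table({"g1": [2, 2, 4]}), min_gene_reads=1)
        np.testing.assert_allclose(norm.to_numpy(), [0.75, 0.75, 1.5])

    def test_uniform_gene_normalises_to_one(self):
        norm = st.codon_density_table(_codon_table({"g1": [5] * 40}), min_gene_reads=1)
        assert (norm == 1.0).all()

    def test_invariant_to_library_scaling(self):
        t = _codon_table({"g1": [1, 2, 3, 10]})
        t2 = t.copy()
        t2["count"] *= 11.0
        pd.testing.assert_series_equal(
            st.codon_density_table(t, 1), st.codon_density_table(t2, 1)
        )

    def test_low_coverage_gene_dropped(self):
        norm = st.codon_density_table(
            _codon_table({"lo": [1, 0, 1], "hi": [40, 30, 30]}), min_gene_reads=64
        )
        assert set(norm.index.get_level_values("transcript_id")) == {"hi"}


class TestFoldDifference:
    def test_arithmetic_and_identity(self):
        a = st.codon_density_table(_codon_table({"g1": [10] * 30}), 1)
        fd = st.fold_difference(a, a, min_codon_index=10)
        assert (fd == 0).all()
        assert (fd.index.get_level_values("codon_index") >= 10).all()

    def test_ratio_arithmetic(self):
        a = st.codon_density_table(_codon_table({"g1": [2, 2, 4] + [2, 2, 4] * 10}), 1)
        b = st.codon_density_table(_codon_table({"g1": [8, 8, 8] + [8, 8, 8] * 10}), 1)
        fd = st.fold_difference(a, b, min_codon_index=10)
        # normA in {0.75, 1.5}, normB = 1: log2fd in {log2(0.75), log2(1.5)}
        assert set(np.round(fd, 6)) == {round(np.log2(0.75), 6), round(np.log2(1.5), 6)}

    def test_swapping_conditions_negates(self):
        rng = np.random.default_rng(0)
        a = st.codon_density_table(_codon_table({"g1": rng.poisson(8, 50) + 1}), 1)
        b = st.codon_density_table(_codon_table({"g1": rng.poisson(8, 50) + 1}), 1)
        np.testing.assert_allclose(
            st.fold_difference(a, b), -st.fold_difference(b, a), atol=1e-12
        )

    def test_site_density_floor(self):
        a = st.codon_density_table(_codon_table({"g1": [0, 0, 0] + [3] * 30}), 1)
        fd = st.fold_difference(a, a, min_site_density=0.25, min_codon_index=0)
        assert 0 not in fd.index.get_level_values("codon_index")


class TestSelection:
    def _fd(self, vals):
        idx = pd.MultiIndex.from_tuples(
            [("g1", 10 + i) for i in range(len(vals))], names=["transcript_id", "codon_index"]
        )
        return pd.Series(vals, index=idx, dtype=float)

    def test_both_replicate_rule(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 200)
        fd1, fd2 = self._fd(base), self._fd(base)
        res = st.select_stall_sites(fd1, fd2)
        z = res["z_1"]
        assert (res.loc[(z > 2) & (res["z_2"] > 2), "selected"] == "high").all()
        assert ((res["selected"] == "high") == ((z > 2) & (res["z_2"] > 2))).all()

    def test_boundary_z_exactly_two_not_selected(self):
        """log2fd [0,0,0,0,10]: the outlier's z is exactly 2 (mean 2, SD 4)."""
        vals = [0.0, 0.0, 0.0, 0.0, 10.0] * 20  # replicate pattern to pass min_sites
        fd = self._fd(vals)
        res = st.select_stall_sites(fd, fd)
        # with the repeated pattern the outliers' z: mean 2, pop sd 4 -> z = 2.0
        out = res[res["log2fd_1"] == 10.0]
        np.testing.assert_allclose(out["z_1"], 2.0)
        assert (out["selected"] == "none").all()

    def test_mixed_z_pair_not_selected(self):
        rng = np.random.default_rng(3)
        fd1 = self._fd(rng.normal(0, 1, 500))
        fd2 = self._fd(rng.normal(0, 1, 500))
        res = st.select_stall_sites(fd1, fd2)
        mixed = (res["z_1"] > 2) & (res["z_2"] <= 2)
        assert (res.loc[mixed, "selected"] == "none").all()

    def test_null_intersection_rate_near_tail_squared(self):
        """Independent null replicates: both-replicate rate ~ per-tail rate^2."""
        rng = np.random.default_rng(4)
        n, reps = 20_000, 5
        n_sel, n_exp = 0, 0.0
        for _ in range(reps):
            fd1 = self._fd(rng.normal(0, 1, n))
            fd2 = self._fd(rng.normal(0, 1, n))
            res = st.select_stall_sites(fd1, fd2)
            n_sel += (res["selected"] == "high").sum()
            n_exp += (res["z_1"] > 2).mean() * (res["z_2"] > 2).mean() * n
        se = np.sqrt(n_exp)  # Poisson-scale check
        assert abs(n_sel - n_exp) < 4 * se + 2

    def test_zero_variance_warns_and_selects_nothing(self):
        fd = self._fd([1.0] * 200)
        with pytest.warns(UserWarning, match="zero variance"):
            res = st.select_stall_sites(fd, fd)
        assert (res["selected"] == "none").all()


class TestContext:
    def _setup(self):
        # ORF: ATG + 30 codons + stop; place known codons at index 20 context
        codons = ["ATG"] + ["GCT"] * 30 + ["TAA"]
        codons[15:22] = ["TGG", "TTT", "GAA", "GAT", "AAA", "CCA", "CAC"]  # -5..+1 of site 20
        orf = "".join(codons)
        seq = "A" * 10 + orf + "T" * 10
        ann = rio.make_annotation([("g1", 10, 10 + len(orf), len(seq))])
        return ann, {"g1": seq}

    def test_hand_built_context_matrix(self):
        ann, seqs = self._setup()
        idx = pd.MultiIndex.from_tuples([("g1", 20)], names=["transcript_id", "codon_index"])
        mat = st.extract_context(idx, ann, seqs)
        assert list(mat.loc[("g1", 20)]) == ["W", "F", "E", "D", "K", "P", "H"]
        assert mat.loc[("g1", 20), 0] == "P"  # P-site CCA -> proline

    def test_window_bounds(self):
        ann, seqs = self._setup()
        idx = pd.MultiIndex.from_tuples(
            [("g1", 12), ("g1", 30)], names=["transcript_id", "codon_index"]
        )
        mat = st.extract_context(idx, ann, seqs)
        assert ("g1", 12) in mat.index  # 12 - 5 = 7 >= 0: retained
        assert ("g1", 30) not in mat.index  # +1 would be the stop codon: dropped

    def test_non_acgt_codon_dropped(self):
        ann, seqs = self._setup()
        seqs = {"g1": seqs["g1"][:40] + "N" + seqs["g1"][41:]}
        idx = pd.MultiIndex.from_tuples([("g1", 12)], names=["transcript_id", "codon_index"])
        assert len(st.extract_context(idx, ann, seqs)) == 0


class TestLogoEnrichment:
    def test_knife_edge_cell_is_zero(self):
        assert st.significance_threshold(alpha=0.5, n_tests=1) == pytest.approx(0.0)
        # n=1, k=1, p=0.5: upper tail 0.5 -> log10-odds 0
        fg = pd.DataFrame({0: ["A"]})
        bg = pd.DataFrame({0: pd.Series(1 / 20, index=list(st.AMINO_ACIDS))})
        bg.loc["A", 0] = 0.5
        cells = st.logo_enrichment(fg, bg, min_foreground=1)
        assert cells.loc[(0, "A"), "log10_odds"] == pytest.approx(0.0)

    def test_exact_binomial_hand_case(self):
        """n=4, k=4, p=0.5: tail 1/16, log10-odds log10(15) ~ 1.176."""
        fg = pd.DataFrame({0: ["A", "A", "A", "A"]})
        bg = pd.DataFrame({0: pd.Series(0.5, index=list(st.AMINO_ACIDS))})
        cells = st.logo_enrichment(fg, bg, min_foreground=1)
        assert cells.loc[(0, "A"), "log10_odds"] == pytest.approx(np.log10(15.0), rel=1e-12)

    def test_matches_bruteforce_pmf_summation_on_full_grid(self):
        """Every cell of a 20 x 7 matrix (n = 50) agrees with a brute-force
        oracle that sums binomial pmf terms, to 1e-10 relative."""
        rng = np.random.default_rng(6)
        n = 50
        fg = pd.DataFrame(
            {p: rng.choice(list(st.AMINO_ACIDS), size=n) for p in st.CONTEXT_POSITIONS}
        )
        bg_raw = rng.dirichlet(np.ones(20), size=len(st.CONTEXT_POSITIONS)).T
        bg = pd.DataFrame(bg_raw, index=list(st.AMINO_ACIDS), columns=st.CONTEXT_POSITIONS)
        cells = st.logo_enrichment(fg, bg)
        assert len(cells) == 140
        for (posn, aa), row in cells.iterrows():
            k, p = int(row["k"]), row["p_bg"]
            pmf = np.array([binom.pmf(j, n, p) for j in range(n + 1)])
            if k / n > p:
                tail = pmf[k:].sum()
                expected = -np.log10(tail / (1 - tail))
            else:
                tail = pmf[: k + 1].sum()
                expected = np.log10(tail / (1 - tail))
            assert row["log10_odds"] == pytest.approx(expected, rel=1e-10, abs=1e-10)
            # away from the knife edge the sign tracks the direction
            if abs(row["log10_odds"]) >= 1.0:
                assert (row["log10_odds"] > 0) == (k / n > p)

    def test_minimum_foreground_enforced(self):
        fg = pd.DataFrame({0: ["A"] * 5})
        bg = pd.DataFrame({0: pd.Series(1 / 20, index=list(st.AMINO_ACIDS))})
        with pytest.raises(ValueError, match="foreground"):
            st.logo_enrichment(fg, bg)


class TestThreshold:
    def test_bonferroni_threshold_reference_value(self):
        """alpha 0.05 over 140 tests gives the published 3.45 log10-odds bar."""
        assert st.significance_threshold(0.05, 140) == pytest.approx(3.45, abs=0.005)

    def test_single_test_arithmetic(self):
        assert st.significance_threshold(0.05, 1) == pytest.approx(np.log10(19), rel=1e-12)
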