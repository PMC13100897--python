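"""Positional statistics: gradients, subsets, LOESS, permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromocline import cline, synth


class TestDistanceFromEnd:
    @pytest.mark.parametrize(
        "midpoint,length,expected",
        [(1e6, 10e6, 1e6), (7e6, 10e6, 3e6), (5e6, 10e6, 5e6)],
    )
    def test_examples(self, midpoint, length, expected):
        assert cline.distance_from_end(midpoint, length) == expected

    @given(st.floats(min_value=1, max_value=9_999_999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reflection_invariance(self, midpoint):
        L = 10_000_000
        assert cline.distance_from_end(midpoint, L) == pytest.approx(
            cline.distance_from_end(L - midpoint, L)
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cline.distance_from_end(0, 1e6)
        with pytest.raises(ValueError):
            cline.distance_from_end(2e6, 1e6)


class TestChromosomeSummaries:
    def _genes(self, counts):
        rows = []
        for chrom, n in counts.items():
            for i in range(n):
                rows.append({"gene_id": f"{chrom}_{i}", "chrom": chrom,
                             "ds": 0.05 + 0.01 * (i % 3), "dn": 0.02,
                             "omega": 0.3, "length": 10_000_000})
        return pd.DataFrame(rows)

    def test_more_than_ten_rule_is_strict(self):
        summ = cline.chromosome_summaries(self._genes({"a": 10, "b": 11}), 10)
        by = summ.set_index("chrom")
        assert not by.loc["a", "included"]
        assert by.loc["b", "included"]

    def test_median_value(self):
        genes = pd.DataFrame({
            "gene_id": list("abc"), "chrom": "c",
            "ds": [0.05, 0.07, 0.09], "dn": [0.01] * 3, "omega": [0.2] * 3,
        })
        summ = cline.chromosome_summaries(genes, 0)
        assert summ.loc[0, "ds"] == pytest.approx(0.07)


class TestLengthRegression:
    def _summaries(self, lengths, medians):
        return pd.DataFrame({
            "chrom": [f"c{i}" for i in range(len(lengths))],
            "length": lengths, "ds": medians,
            "n_genes": 50, "included": True,
            "chrom_class": "autosome",
        })

    def test_exact_power_law_recovered(self):
        lengths = np.geomspace(1e7, 2e8, 12)
        medians = 5.0 * lengths ** -0.31
        res = cline.length_rate_regression(self._summaries(lengths, medians))
        assert res.slope == pytest.approx(-0.31, abs=1e-10)
        assert res.p_value < 1e-10

    def test_cline_genome_negative_and_null_flat(self, study_karyotype):
        p_cline = synth.ClineParams(x_factor=1.0)
        g = synth.simulate_gene_rates(study_karyotype, p_cline, 2.0, seed=0)
        summ = cline.chromosome_summaries(g, 10)
        res = cline.length_rate_regression(summ)
        assert res.slope < 0 and res.p_value < 0.05
        # flat dS law: slope should usually be non-significant
        p_flat = synth.ClineParams(ds_center=0.08, ds_end=0.08, x_factor=1.0)
        hits = 0
        for seed in range(30):
            g = synth.simulate_gene_rates(study_karyotype, p_flat, 1.0, seed=seed)
            summ = cline.chromosome_summaries(g, 10)
            res = cline.length_rate_regression(summ)
            hits += res.p_value < 0.05
        assert hits <= 4  # ~5% nominal, allow generous Monte-Carlo slack

    def test_nonpositive_medians_dropped_with_warning(self):
        lengths = np.geomspace(1e7, 1e8, 6)
        medians = [0.1, 0.09, 0.0, 0.08, 0.07, 0.06]
        with pytest.warns(UserWarning):
            res = cline.length_rate_regression(self._summaries(lengths, medians))
        assert res.n == 5


class TestPositionRegressions:
    def test_strictly_decreasing_response_all_negative(self, study_karyotype):
        rng = np.random.default_rng(0)
        rows = []
        for rec in list(study_karyotype)[:10]:
            pos = rng.uniform(1, rec.length - 1, 30)
            d = np.minimum(pos, rec.length - pos)
            rows.append(pd.DataFrame({
                "gene_id": [f"{rec.id}_{i}" for i in range(30)],
                "chrom": rec.id, "midpoint": pos, "length": rec.length,
                "distance_from_end": d, "ds": 0.1 - 1e-10 * d,
            }))
        genes = pd.concat(rows, ignore_index=True)
        per_chrom, tally, pooled = cline.position_regressions(genes)
        assert tally.n_negative == 10 and tally.n_positive == 0
        assert pooled.slope < 0

    def test_null_tally_balanced(self, study_karyotype):
        p_flat = synth.ClineParams(ds_center=0.08, ds_end=0.08, x_factor=1.0)
        negs, sigs, total = 0, 0, 0
        for seed in range(10):
            g = synth.simulate_gene_rates(study_karyotype, p_flat, 1.0, seed=seed)
            per_chrom, tally, _ = cline.position_regressions(g)
            negs += tally.n_negative
            sigs += tally.n_negative_significant + tally.n_positive_significant
            total += tally.n_total
        assert 0.35 <= negs / total <= 0.65
        assert sigs / total <= 0.12

    def test_cline_genome_mostly_negative(self, default_gene_table):
        per_chrom, tally, pooled = cline.position_regressions(default_gene_table)
        big = per_chrom[per_chrom["n"] >= 10]
        frac_neg = (big["slope"] < 0).mean()
        assert frac_neg >= 0.7
        assert pooled.slope < 0 and pooled.p_value < 0.05


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        x = np.linspace(0, 50e6, 40)
        y = 0.1 - 2e-9 * x + 1.5e-17 * x**2
        fit = cline.quadratic_fit(x, y)
        assert fit.coef[0] == pytest.approx(0.1, rel=1e-8)
        assert fit.coef[1] == pytest.approx(-2e-9, rel=1e-6)
        assert fit.coef[2] == pytest.approx(1.5e-17, rel=1e-6)
        assert fit.u_shaped

    def test_synthetic_cline_chromosome_u_shaped(self):
        rec = synth.ChromosomeRecord("c", 100_000_000)
        k = synth.Karyotype((rec, synth.ChromosomeRecord("d", 50_000_000)))
        p = synth.ClineParams(x_factor=1.0)
        g = synth.simulate_gene_rates(k, p, 2.0, seed=1)
        sub = g[g["chrom"] == "c"]
        fit = cline.quadratic_fit(sub["midpoint"], sub["ds"])
        assert fit.u_shaped

    def test_flat_response_rarely_u_shaped(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(30):
            x = rng.uniform(0, 1e8, 60)
            y = rng.normal(0.08, 0.01, 60)
            hits += cline.quadratic_fit(x, y).u_shaped
        assert hits <= 4

    def test_degenerate_positions_error(self):
        with pytest.raises(ValueError):
            cline.quadratic_fit([1e6] * 6, [0.1] * 6)


class TestLoess:
    def test_constant_response(self):
        x = np.linspace(0, 10, 30)
        fit = cline.loess_fit(x, np.full(30, 2.5))
        assert np.allclose(fit.fitted, 2.5)
        assert np.allclose(fit.se, 0.0)

    def test_exact_linear_reproduced(self):
        x = np.linspace(0, 10, 40)
        y = 3.0 + 0.7 * x
        fit = cline.loess_fit(x, y)
        assert np.allclose(fit.fitted, y, atol=1e-8)

    def test_matches_pointwise_wls_oracle(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 1, 40))
        y = np.sin(3 * x) + rng.normal(0, 0.05, 40)
        span = 0.5
        fit = cline.loess_fit(x, y, span=span)
        k = int(np.ceil(span * len(x)))
        for idx in (5, 20, 35):
            x0 = x[idx]
            d = np.abs(x - x0)
            dmax = np.sort(d)[k - 1]
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
            X = np.column_stack([np.ones_like(x), x - x0])
            beta = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                                   y * np.sqrt(w), rcond=None)[0]
            assert fit.fitted[idx] == pytest.approx(beta[0], abs=1e-8)

    def test_noisy_parabola_vertex_located(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 200))
        y = (x - 6.0) ** 2 + rng.normal(0, 0.5, 200)
        fit = cline.loess_fit(x, y, span=0.4)
        vertex = fit.x[np.argmin(fit.fitted)]
        assert vertex == pytest.approx(6.0, abs=0.6)

    def test_parameter_errors(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            cline.loess_fit(x, x, span=0.05)
        with pytest.raises(ValueError):
            cline.loess_fit(x[:5], x[:5])


class TestGcStats:
    def test_trivial_sequences_via_fasta(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(
            ">c1\n" + "GC" * 6000 + "\n>c2\n" + "ATGC" * 3000 + "\n"
        )
        gc = cline.gc_from_fasta(fa, window_bp=10_000)
        assert np.allclose(gc.loc[gc["chrom"] == "c1", "gc"], 1.0)
        assert np.allclose(gc.loc[gc["chrom"] == "c2", "gc"], 0.5)

    def test_n_runs_excluded(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c1\n" + "N" * 8000 + "GC" * 1000 + "\n")
        gc = cline.gc_from_fasta(fa, window_bp=10_000)
        assert gc.empty  # >50% N in the single window

    def test_synthetic_gc_cline_negative_slopes(self):
        k = synth.Karyotype((
            synth.ChromosomeRecord("c1", 40_000_000),
            synth.ChromosomeRecord("c2", 25_000_000),
        ))
        neg = 0
        for seed in range(10):
            track = synth.simulate_gc_track(k, 0.41, 0.46, 3e6, 10_000, seed=seed)
            _, regs = cline.gc_window_stats(track, k.lengths)
            neg += (regs["slope"] < 0).all()
        assert neg >= 9


class TestSubsets:
    def _one_gene(self, midpoint, length=30e6):
        return pd.DataFrame({
            "gene_id": ["g"], "chrom": ["c"], "midpoint": [midpoint],
            "length": [length],
            "distance_from_end": [min(midpoint, length - midpoint)],
        })

    def test_ends_mode(self):
        assert len(cline.subset_by_position(self._one_gene(2e6), "ends", 5e6)) == 1
        assert len(cline.subset_by_position(self._one_gene(10e6), "ends", 5e6)) == 0

    def test_center_mode(self):
        assert len(cline.subset_by_position(self._one_gene(10e6), "center", 10e6)) == 1
        assert len(cline.subset_by_position(self._one_gene(2e6), "center", 10e6)) == 0

    def test_short_chromosome_contributes_all_genes_to_center(self):
        g = self._one_gene(1e6, length=4e6)
        assert len(cline.subset_by_position(g, "center", 10e6)) == 1

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            cline.subset_by_position(self._one_gene(1e6), "middle", 1e6)


class TestPermutationTest:
    def test_identical_constant_groups_give_p_one(self):
        values = [0.05] * 40
        labels = [True] * 10 + [False] * 30
        res = cline.permutation_test_groups(values, labels, n_perm=500, seed=0)
        assert res.p_value == 1.0
        assert res.observed == 0.0

    def test_fully_separated_groups_reach_minimal_p(self):
        values = list(np.linspace(0.01, 0.02, 30)) + list(np.linspace(0.1, 0.2, 70))
        labels = [True] * 30 + [False] * 70
        n_perm = 999
        res = cline.permutation_test_groups(values, labels, n_perm=n_perm, seed=1)
        assert res.p_value == pytest.approx(1 / (n_perm + 1))

    def test_p_bounded_below_by_resolution(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=50)
        labels = [True] * 20 + [False] * 30
        res = cline.permutation_test_groups(values, labels, n_perm=99, seed=3)
        assert res.p_value >= 1 / 100

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            cline.permutation_test_groups([1.0, 2.0], [True, True], n_perm=10)

    def test_null_rejection_rate_calibrated(self):
        # labels shuffled onto heterogeneous data: exact test, ~5% rejections
        rng = np.random.default_rng(4)
        rejections = 0
        n_data = 300
        for _ in range(n_data):
            values = rng.gamma(2.0, 0.04, 120)
            labels = np.zeros(120, bool)
            labels[rng.choice(120, 25, replace=False)] = True
            res = cline.permutation_test_groups(
                values, labels, n_perm=199, seed=int(rng.integers(2**31))
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_data <= 0.09

    def test_determinism(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=60)
        labels = [True] * 20 + [False] * 40
        a = cline.permutation_test_groups(values, labels, n_perm=200, seed=7)
        b = cline.permutation_test_groups(values, labels, n_perm=200, seed=7)
        assert a == b


class TestXEffect:
    def test_x_reduction_detected_and_dn_specific(self, default_gene_table):
        xe = cline.x_effect_analysis(default_gene_table, n_perm=999, seed=0)
        xe = xe.set_index(["subset", "response"])
        assert xe.loc[("all", "ds"), "p_value"] < 0.05
        assert xe.loc[("ends", "ds"), "p_value"] < 0.05
        assert xe.loc[("all", "ds"), "observed_diff"] < 0
        assert xe.loc[("ends", "dn"), "p_value"] > 0.05

    def test_requires_class_column(self):
        genes = pd.DataFrame({"ds": [0.1], "dn": [0.02], "omega": [0.2]})
        with pytest.raises(ValueError):
            cline.x_effect_analysis(genes, n_perm=10)


class TestModelInterface:
    def test_fit_summary_and_tables(self, study_karyotype, default_gene_table):
        model = cline.ChromoclineModel(default_gene_table, study_karyotype)
        res = model.fit(n_perm=499, seed=1)
        text = res.summary()
        assert "Length effect" in text and "X vs autosomes" in text
        assert set(res.length_regressions) == {"all", "ends", "center"}
        assert res.position_tally.n_total > 0
        assert res.x_effect is not None

    def test_determinism_given_seed(self, study_karyotype, default_gene_table):
        model = cline.ChromoclineModel(default_gene_table, study_karyotype)
        a = model.fit(n_perm=299, seed=5)
        b = model.fit(n_perm=299, seed=5)
        pd.testing.assert_frame_equal(a.x_effect, b.x_effect)
        assert a.position_tally == b.position_tally

    def test_plots_return_axes(self, study_karyotype, default_gene_table):
        import matplotlib

        matplotlib.use("Agg")
        model = cline.ChromoclineModel(default_gene_table, study_karyotype)
        res = model.fit(n_perm=99, seed=0)
        assert res.plot_length_effect() is not None
        assert res.plot_x_boxplot() is not None
        chrom = res.position_per_chrom.iloc[0]["chrom"]
        assert res.plot_chromosome(chrom) is not None
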