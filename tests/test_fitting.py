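"""Design construction, least-squares recovery, and the synthetic generator."""

import numpy as np
import pytest

from crowdnn.fitting import (
    DESIGN_COLUMNS,
    FitError,
    NOISE_REL_DG37,
    build_design,
    design_row,
    fit_parameters,
    simulate_duplex_set,
    simulate_melting_dataset,
)
from crowdnn.sequences import DuplexSpec, nn_steps
from crowdnn.thermo import predict_duplex


class TestDesign:
    def test_all_ten_stacks_row(self):
        row = dict(zip(DESIGN_COLUMNS, design_row(DuplexSpec("GAUUACGCCUG"))))
        for step in DESIGN_COLUMNS[:10]:
            assert row[step] == 1.0
        assert row["initiation"] == 1.0
        assert row["terminal_AU"] == 0.0

    def test_identical_nn_multisets_identical_rows(self):
        # a duplicate pair: same NN multiset, different sequences
        r1 = design_row(DuplexSpec("GGCUGUUC"))
        r2 = design_row(DuplexSpec("GGUUCUGC"))
        assert np.array_equal(r1, r2)

    def test_too_few_duplexes_unidentifiable(self, table1):
        sim = simulate_duplex_set(table1, 3, count=20, n_self_complementary=5)
        with pytest.raises(FitError, match="identify"):
            build_design(list(sim.duplexes)[:11])

    def test_rank_deficiency_names_combinations(self):
        # 12 copies of one duplex: plenty of rows, rank 3
        dups = [DuplexSpec("GAUUACGCCUG")] * 12
        with pytest.raises(FitError, match="rank-deficient"):
            build_design(dups)

    def test_full_rank_reported(self, table1):
        sim = simulate_duplex_set(table1, 5)
        design = build_design(list(sim.duplexes))
        assert design.rank == 12
        assert np.isfinite(design.condition_number)


class TestRecovery:
    def test_noiseless_exact_recovery(self, table1):
        sim = simulate_duplex_set(
            table1, 11, noise_rel_dG37=0.0, noise_rel_dH=0.0
        )
        design = build_design(list(sim.duplexes))
        result = fit_parameters(design, sim.dG37, sim.dH)
        for q in DESIGN_COLUMNS:
            assert result.parameters[q].dG37 == pytest.approx(
                table1[q].dG37, abs=1e-9
            ), q
            assert result.parameters[q].dH == pytest.approx(
                table1[q].dH, abs=1e-9
            ), q
        assert result.summary["mean_pct_diff_dG37"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_rmse(self, table1):
        # abs noise sigma(dG)=0.3, sigma(dH)=3; aggregate per-parameter dG37
        # RMSE < 0.15 kcal/mol (oracle over 200 replicates: 0.097 mean)
        sq = []
        for seed in range(30):
            sim = simulate_duplex_set(
                table1, seed, noise_abs_dG37=0.3, noise_abs_dH=3.0
            )
            design = build_design(list(sim.duplexes))
            res = fit_parameters(design, sim.dG37, sim.dH)
            sq.extend(
                (res.parameters[q].dG37 - table1[q].dG37) ** 2
                for q in DESIGN_COLUMNS
            )
        assert np.sqrt(np.mean(sq)) < 0.15

    def test_estimator_unbiased(self, table1):
        """Mean parameter error over seeded replicates is ~0 under 0-mean noise."""
        errs = []
        for seed in range(60):
            sim = simulate_duplex_set(
                table1, seed, noise_abs_dG37=0.3, noise_abs_dH=3.0
            )
            design = build_design(list(sim.duplexes))
            res = fit_parameters(design, sim.dG37, sim.dH)
            errs.extend(
                res.parameters[q].dG37 - table1[q].dG37 for q in DESIGN_COLUMNS
            )
        # MC standard error of the mean is ~0.1/sqrt(720) ~ 0.004
        assert abs(np.mean(errs)) < 0.02

    def test_entropy_derived_from_both_fits(self, table1):
        sim = simulate_duplex_set(table1, 7, noise_rel_dG37=0.0, noise_rel_dH=0.0)
        design = build_design(list(sim.duplexes))
        res = fit_parameters(design, sim.dG37, sim.dH)
        for q in DESIGN_COLUMNS:
            t = res.parameters[q]
            assert t.dG37 == pytest.approx(t.dH - 310.15 * t.dS, abs=1e-9)

    def test_symmetry_held_fixed(self, table1):
        sim = simulate_duplex_set(table1, 13)
        design = build_design(list(sim.duplexes))
        res = fit_parameters(design, sim.dG37, sim.dH)
        assert res.parameters["symmetry"].dG37 == 0.43

    def test_nonfinite_responses_rejected(self, table1):
        sim = simulate_duplex_set(table1, 17)
        design = build_design(list(sim.duplexes))
        bad = sim.dG37.copy()
        bad[0] = np.nan
        with pytest.raises(FitError, match="non-finite"):
            fit_parameters(design, bad, sim.dH)


class TestGenerator:
    def test_noise_zero_equals_predictions(self, table1):
        sim = simulate_duplex_set(table1, 19, noise_rel_dG37=0.0, noise_rel_dH=0.0)
        for dup, g in zip(sim.duplexes, sim.dG37):
            assert predict_duplex(dup, table1).dG37 == pytest.approx(g)

    def test_reproducible_under_seed(self, table1):
        a = simulate_duplex_set(table1, 23)
        b = simulate_duplex_set(table1, 23)
        assert [d.top_strand for d in a.duplexes] == [
            d.top_strand for d in b.duplexes
        ]
        assert np.array_equal(a.dG37, b.dG37)

    def test_panel_composition_and_coverage(self, table1):
        sim = simulate_duplex_set(table1, 29)
        assert len(sim.duplexes) == 45
        n_self = sum(d.self_complementary for d in sim.duplexes)
        assert n_self == 20
        lengths = {d.n_bp for d in sim.duplexes}
        assert lengths <= set(range(6, 13))
        coverage = {s: 0 for s in DESIGN_COLUMNS[:10]}
        for d in sim.duplexes:
            for s in set(nn_steps(d)):
                coverage[s] += 1
        assert min(coverage.values()) >= 5

    def test_stability_selection(self, table1):
        sim = simulate_duplex_set(table1, 31)
        assert (sim.table["dG37_true"] <= -4.0).all()

    def test_melting_series_mirrors_experimental_design(self, table1):
        t = predict_duplex(DuplexSpec("GGCUGUUC"), table1)
        data = simulate_melting_dataset(t, 4, seed=37, fold_range=100, n_points=12)
        assert len(data.ct) == 12
        assert max(data.ct) / min(data.ct) == pytest.approx(100.0)
        assert data.tm == tuple(sorted(data.tm))  # Tm grows with Ct
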