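"""Specification search: decision rules, search paths, ladder tables."""

import numpy as np
import pytest

from lgmsearch.fit import FitResult
from lgmsearch.model import polynomial_loadings
from lgmsearch.population import Dataset, PopulationCondition, generate_dataset
from lgmsearch.search import (
    SearchOptions,
    StartingModel,
    compare_models,
    ladder_report,
    run_search,
)


def _fake_fit(**kw):
    base = dict(
        spec=None, estimates=None, loglik=0.0, k=1, df=1, n=100,
        converged=True, chi_square=0.0, aic=0.0, bic=0.0,
        mu_hat=np.zeros(2), sigma_hat=np.eye(2),
        sample_mean=np.zeros(2), sample_cov=np.eye(2),
        cfi=1.0, rmsea=0.0, srmr=0.0,
    )
    base.update(kw)
    return FitResult(**base)


class TestCompareModels:
    @pytest.mark.parametrize(
        "criterion, simple_kw, complex_kw, expected",
        [
            # the applied ladder: quadratic vs cubic information criteria
            ("aic", {"aic": 24_407.0}, {"aic": 24_400.0}, "complex"),
            ("bic", {"bic": 24_513.0}, {"bic": 24_510.0}, "complex"),
            ("aic", {"aic": 100.0}, {"aic": 96.1}, "simpler"),  # delta 3.9 < 4
            ("bic", {"bic": 100.0}, {"bic": 98.1}, "simpler"),
            ("cfi", {"cfi": 0.95}, {"cfi": 0.961}, "complex"),
            ("cfi", {"cfi": 0.95}, {"cfi": 0.959}, "simpler"),
            ("rmsea", {"rmsea": 0.06}, {"rmsea": 0.044}, "complex"),
            ("srmr", {"srmr": 0.05}, {"srmr": 0.041}, "simpler"),
        ],
    )
    def test_threshold_arithmetic(self, criterion, simple_kw, complex_kw, expected):
        decision, _, flagged = compare_models(
            _fake_fit(**simple_kw), _fake_fit(**complex_kw), criterion
        )
        assert decision == expected and not flagged

    def test_lrt_uses_alpha_level(self):
        simple = _fake_fit(loglik=-1000.0, df=5)
        complex_ = _fake_fit(loglik=-997.0, df=4)  # delta chi2 = 6 > 3.84
        decision, p, _ = compare_models(simple, complex_, "lrt")
        assert decision == "complex" and p < 0.05

    def test_nonconvergence_flags_and_keeps_simpler(self):
        decision, _, flagged = compare_models(
            _fake_fit(aic=100.0), _fake_fit(aic=0.0, converged=False), "aic"
        )
        assert decision == "simpler" and flagged


class TestStartingModels:
    def test_fixed_id_mapping(self):
        table = {
            1: ("simplest", "ID", "step_up"),
            2: ("most_complex", "ID", "top_down"),
            3: ("simplest", "UN", "step_up"),
            4: ("most_complex", "UN", "top_down"),
        }
        for sid, (mean_start, residual, direction) in table.items():
            start = StartingModel(sid)
            assert start.mean_start == mean_start
            assert start.residual_structure == residual
            assert start.direction == direction

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="1-4"):
            StartingModel(5)


@pytest.fixture(scope="module")
def linear_dataset():
    return generate_dataset(PopulationCondition("linear4", "UN1", 0.3, 210), 77)


class TestRunSearch:
    def test_bic_consistency_for_intercept_only_population(self):
        # flat population: y = 1 + zeta + eps, zeta ~ N(0, 0.2), eps ~ N(0, I)
        hits = 0
        reps = 100
        rng = np.random.default_rng(555)
        for _ in range(reps):
            zeta = rng.normal(0.0, np.sqrt(0.2), size=(390, 1))
            y = 1.0 + zeta + rng.standard_normal((390, 4))
            result = run_search(Dataset(y=y), 4, "bic")
            hits += result.selected_order == 0
        assert hits >= 95

    def test_trace_length_bounded_by_ladder(self, linear_dataset):
        result = run_search(linear_dataset, 3, "bic")
        assert len(result.trace) <= linear_dataset.n_waves - 2
        assert 0 <= result.selected_order <= linear_dataset.n_waves - 2

    def test_row_permutation_invariance(self, linear_dataset):
        rng = np.random.default_rng(8)
        perm = rng.permutation(linear_dataset.n)
        shuffled = Dataset(y=linear_dataset.y[perm])
        for criterion in ("bic", "lrt", "srmr"):
            a = run_search(linear_dataset, 4, criterion)
            b = run_search(shuffled, 4, criterion)
            assert a.selected_order == b.selected_order
            np.testing.assert_allclose(
                [s.statistic for s in a.trace],
                [s.statistic for s in b.trace],
                rtol=1e-4, atol=1e-7,
            )

    def test_shared_cache_reuses_fits(self, linear_dataset, monkeypatch):
        import lgmsearch.search as search_mod

        calls = []
        real = search_mod.fit_ml

        def counting(dataset, spec, options=None):
            calls.append(spec.mean_order)
            return real(dataset, spec, options)

        monkeypatch.setattr(search_mod, "fit_ml", counting)
        cache = {}
        for criterion in ("bic", "aic", "lrt", "cfi", "rmsea", "srmr"):
            run_search(linear_dataset, 4, criterion, cache=cache)
        # at most one fit per distinct order, however many criteria ran
        assert len(calls) == len(set(calls))
        assert len(calls) <= linear_dataset.n_waves - 1

    def test_step_up_equals_top_down_when_decisions_unanimous(self, ladder_tools):
        # datasets whose full decision ladder is threshold-shaped must give
        # the same selection from both directions (models 3 and 4)
        ladder_decisions, threshold_shaped = ladder_tools
        agreements = checked = 0
        for seed in range(12):
            data = generate_dataset(
                PopulationCondition("linear4", "AR1", 0.1, 210), 900 + seed
            )
            if not threshold_shaped(ladder_decisions(data, "bic")):
                continue  # decisions not unanimous along the ladder
            checked += 1
            up = run_search(data, 3, "bic")
            down = run_search(data, 4, "bic")
            if up.selected_order == down.selected_order:
                agreements += 1
        assert checked > 0 and agreements == checked


class TestLadderReport:
    def test_single_order_table(self, linear_dataset):
        table = ladder_report(linear_dataset, "UN", orders=[0])
        assert len(table) == 1
        assert table.loc[0, "order"] == 0

    def test_aic_column_recomputable(self, linear_dataset):
        table = ladder_report(linear_dataset, "UN")
        np.testing.assert_allclose(
            table["aic"], -2 * table["loglik"] + 2 * table["k"], rtol=1e-12
        )

    def test_cubic_mean_population_selects_cubic_by_aic(self):
        # six-wave population with a genuine cubic mean (fall then rise),
        # subject-level intercept/slope heterogeneity and level-1 noise:
        # the quartic term should not improve AIC, the cubic one should
        lam = polynomial_loadings(6, 3)
        alpha = np.array([10.0, -4.0, 1.2, -0.10])
        rng = np.random.default_rng(42)
        picked_cubic = 0
        reps = 10
        for _ in range(reps):
            eta = rng.multivariate_normal(
                [0, 0], [[9.0, 0.5], [0.5, 0.4]], size=602
            )
            y = (
                lam @ alpha
                + eta @ polynomial_loadings(6, 1).T
                + rng.standard_normal((602, 6)) * 4.0
            )
            table = ladder_report(y, "UN", orders=range(0, 5))
            aic = table.set_index("order")["aic"]
            quartic_gain = aic[3] - aic[4]
            cubic_gain = aic[2] - aic[3]
            if quartic_gain < 4.0 and cubic_gain >= 4.0:
                picked_cubic += 1
        assert picked_cubic >= reps * 0.7
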