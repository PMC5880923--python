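import numpy as np
import pytest

from lgmsearch.model import polynomial_loadings


def iterative_gls(ybar, S, order, n_waves, tol=1e-13, max_iter=1000):
    """Independent oracle for ML with an unstructured residual covariance
    and a fixed polynomial mean order: alternate the feasible-GLS mean
    estimate and the covariance update

        alpha = (L' Sig^-1 L)^-1 L' Sig^-1 ybar
        Sig   = S + (ybar - L alpha)(ybar - L alpha)'

    to its fixed point.  Deliberately a different algorithm from the
    package's gradient-based optimizer.
    """
    lam = polynomial_loadings(n_waves, order)
    alpha = np.linalg.lstsq(lam, ybar, rcond=None)[0]
    for _ in range(max_iter):
        d = ybar - lam @ alpha
        sigma = S + np.outer(d, d)
        si = np.linalg.inv(sigma)
        new_alpha = np.linalg.solve(lam.T @ si @ lam, lam.T @ si @ ybar)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    d = ybar - lam @ alpha
    return alpha, S + np.outer(d, d)


def un_ladder_decisions(y, criterion, max_order=None):
    """Recompute every adjacent-order decision of a UN-residual ladder
    directly from the public fitting API (independent of run_search's
    internal caching).  Returns the list of decisions for pairs
    (0,1), (1,2), ..., (max_order-1, max_order)."""
    from lgmsearch.fit import baseline_fit, fit_indices, fit_ml
    from lgmsearch.model import ModelSpec
    from lgmsearch.search import compare_models

    arr = np.asarray(getattr(y, "y", y))
    t = arr.shape[1]
    if max_order is None:
        max_order = t - 2
    base = baseline_fit(arr)
    fits = [
        fit_indices(fit_ml(arr, ModelSpec(t, q, "UN", "none")), base)
        for q in range(max_order + 1)
    ]
    return [
        compare_models(fits[q], fits[q + 1], criterion)[0]
        for q in range(max_order)
    ]


def is_threshold_shaped(decisions):
    """True when the decision profile is complex,...,complex,simpler,...:
    the unanimity condition under which both search directions must
    select the same order (the threshold)."""
    seen_simpler = False
    for d in decisions:
        if d == "simpler":
            seen_simpler = True
        elif seen_simpler:
            return False
    return True


@pytest.fixture(scope="session")
def gls_oracle():
    return iterative_gls


@pytest.fixture(scope="session")
def ladder_tools():
    return un_ladder_decisions, is_threshold_shaped


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
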