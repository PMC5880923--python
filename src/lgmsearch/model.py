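"""Analysis-model structure for polynomial latent growth models.

A latent growth model (LGM) for ``t`` repeated measures expresses the
outcome vector as ``y = Lambda @ eta + eps``: ``Lambda`` holds polynomial
time codes, ``eta`` the subject's growth factors (intercept, slope, ...)
and ``eps`` the wave-specific residuals.  With factor means ``alpha``,
between-subject factor covariance ``Psi`` and residual covariance
``Theta`` the implied moments of ``y`` are

    mu    = Lambda @ alpha
    Sigma = Lambda_r @ Psi @ Lambda_r' + Theta

where ``Lambda_r`` covers only the factors given random effects.  The
measurement intercepts are fixed to zero for identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "RESIDUAL_STRUCTURES",
    "RANDOM_EFFECTS_POLICIES",
    "ModelSpec",
    "ParamVector",
    "ImpliedMoments",
    "ParamCount",
    "polynomial_loadings",
    "build_theta",
    "implied_moments",
    "count_free_parameters",
]

#: Within-subject residual covariance families.
#: ID   — one common variance, zero covariances;
#: AR1  — common variance with exponentially decaying correlation rho^|i-j|;
#: UN1  — one free variance per wave, zero covariances (banded main diagonal);
#: UN   — fully unstructured t x t covariance.
RESIDUAL_STRUCTURES = ("ID", "AR1", "UN1", "UN")

RANDOM_EFFECTS_POLICIES = ("full_identified", "match_mean", "none")

_PSD_TOL = 1e-10


def polynomial_loadings(n_waves: int, order: int) -> np.ndarray:
    """Polynomial loading matrix with time codes 0, 1, ..., t-1.

    Entry ``(i, j)`` is ``i**j`` (with ``0**0 = 1``), so the first column
    is all ones (intercept) and the intercept refers to first-wave status.

    Parameters
    ----------
    n_waves
        Number of repeated measures ``t`` (>= 1).
    order
        Highest polynomial power ``q``; the matrix has ``q + 1`` columns.

    Returns
    -------
    ndarray of shape ``(n_waves, order + 1)``.
    """
    if n_waves < 1:
        raise ValueError(f"n_waves must be >= 1, got {n_waves}")
    if not 0 <= order <= n_waves - 1:
        raise ValueError(
            f"mean order must satisfy 0 <= order <= n_waves - 1 = "
            f"{n_waves - 1}, got {order}"
        )
    times = np.arange(n_waves, dtype=float)
    powers = np.arange(order + 1)
    with np.errstate(invalid="ignore"):
        lam = times[:, None] ** powers[None, :]
    lam[0, 0] = 1.0  # 0**0
    return lam


def _n_theta_params(structure: str, n_waves: int) -> int:
    if structure == "ID":
        return 1
    if structure == "AR1":
        return 2
    if structure == "UN1":
        return n_waves
    if structure == "UN":
        return n_waves * (n_waves + 1) // 2
    raise ValueError(
        f"unknown residual structure {structure!r}; "
        f"expected one of {RESIDUAL_STRUCTURES}"
    )


@dataclass(frozen=True)
class ModelSpec:
    """An analysis model: waves, polynomial mean order, residual family.

    ``random_effects_policy`` controls the between-subject covariance Psi:

    ``full_identified`` (default)
        Psi spans the largest leading block of the included growth factors
        that keeps the model identified by moment counting (higher-order
        factors keep a mean but lose their random effect).  With an UN
        residual structure this truncates to no random effects at all,
        because a free Theta absorbs any Lambda Psi Lambda' contribution.
    ``match_mean``
        Psi spans every included factor; raises if that is unidentified.
    ``none``
        Fixed-effects mean structure, no Psi term.
    """

    n_waves: int
    mean_order: int
    residual_structure: str = "ID"
    random_effects_policy: str = "full_identified"
    covariate_included: bool = False

    def __post_init__(self) -> None:
        if self.n_waves < 3:
            raise ValueError(f"n_waves must be >= 3, got {self.n_waves}")
        if not 0 <= self.mean_order <= self.n_waves - 1:
            raise ValueError(
                f"mean order must satisfy 0 <= order <= n_waves - 1 = "
                f"{self.n_waves - 1}, got {self.mean_order}"
            )
        if self.residual_structure not in RESIDUAL_STRUCTURES:
            raise ValueError(
                f"unknown residual structure {self.residual_structure!r}; "
                f"expected one of {RESIDUAL_STRUCTURES}"
            )
        if self.random_effects_policy not in RANDOM_EFFECTS_POLICIES:
            raise ValueError(
                f"unknown random-effects policy "
                f"{self.random_effects_policy!r}; "
                f"expected one of {RANDOM_EFFECTS_POLICIES}"
            )
        if self.covariate_included:
            raise NotImplementedError(
                "search models are unconditional; covariate_included must "
                "be False"
            )
        self.n_random_effects  # validates identification

    # ---- derived structure -------------------------------------------------

    @property
    def n_factors(self) -> int:
        return self.mean_order + 1

    @property
    def n_moments(self) -> int:
        t = self.n_waves
        return t + t * (t + 1) // 2

    @property
    def n_theta_params(self) -> int:
        return _n_theta_params(self.residual_structure, self.n_waves)

    def _k_for_r(self, r: int) -> int:
        return self.n_factors + r * (r + 1) // 2 + self.n_theta_params

    @property
    def is_saturated(self) -> bool:
        return (
            self.mean_order == self.n_waves - 1
            and self.residual_structure == "UN"
            and self.n_random_effects == 0
        )

    @property
    def n_random_effects(self) -> int:
        """Dimension of Psi under the spec's random-effects policy."""
        policy = self.random_effects_policy
        if policy == "none":
            return 0
        # a free UN Theta is not identified jointly with any Psi block
        cap = 0 if self.residual_structure == "UN" else self.n_waves - 1
        r_full = min(self.n_factors, cap)
        if policy == "match_mean":
            r = min(self.n_factors, self.n_waves - 1)
            if self.residual_structure == "UN" or r < self.n_factors:
                raise ValueError(
                    "match_mean random effects are not identified for "
                    f"{self.residual_structure} residuals with mean order "
                    f"{self.mean_order} at {self.n_waves} waves"
                )
            if self._k_for_r(r) >= self.n_moments:
                raise ValueError(
                    "match_mean random effects exceed the observed moment "
                    f"count at {self.n_waves} waves, mean order "
                    f"{self.mean_order}"
                )
            return r
        # full_identified: largest leading block passing moment counting
        for r in range(r_full, -1, -1):
            k = self._k_for_r(r)
            if k < self.n_moments or (k == self.n_moments and self._saturated_at(r)):
                return r
        raise ValueError(  # pragma: no cover - unreachable for valid specs
            f"no identified random-effects block for {self}"
        )

    def _saturated_at(self, r: int) -> bool:
        return (
            self.mean_order == self.n_waves - 1
            and self.residual_structure == "UN"
            and r == 0
        )

    # ---- config round-trip -------------------------------------------------

    def to_config(self) -> dict:
        return {
            "waves": self.n_waves,
            "order": self.mean_order,
            "residual": self.residual_structure,
            "repolicy": self.random_effects_policy,
        }

    @classmethod
    def from_config(cls, config: dict) -> "ModelSpec":
        return cls(
            n_waves=int(config["waves"]),
            mean_order=int(config["order"]),
            residual_structure=str(config.get("residual", "ID")),
            random_effects_policy=str(
                config.get("repolicy", "full_identified")
            ),
        )


class ParamCount(NamedTuple):
    """Free parameters ``k`` and model degrees of freedom ``df``."""

    k: int
    df: int


def count_free_parameters(spec: ModelSpec) -> ParamCount:
    """Count free parameters and the chi-square degrees of freedom.

    ``k`` sums the factor means, the free elements of Psi and the free
    residual parameters; ``df = t + t(t+1)/2 - k`` counts the observed
    first and second moments not consumed by the model.
    """
    r = spec.n_random_effects
    k = spec._k_for_r(r)
    return ParamCount(k=k, df=spec.n_moments - k)


def build_theta(structure: str, n_waves: int, theta) -> np.ndarray:
    """Assemble the t x t residual covariance from its free parameters.

    ``theta`` is structure-specific: ID — scalar variance; AR1 — pair
    ``(variance, rho)``; UN1 — length-t variance vector; UN — full t x t
    symmetric matrix (or its lower-triangle vector, row-major).
    """
    t = n_waves
    if structure == "ID":
        variance = float(np.asarray(theta).reshape(()))
        if variance <= 0:
            raise ValueError(f"ID residual variance must be > 0, got {variance}")
        return variance * np.eye(t)
    if structure == "AR1":
        variance, rho = (float(v) for v in np.asarray(theta).ravel())
        if variance <= 0:
            raise ValueError(f"AR1 residual variance must be > 0, got {variance}")
        if not -1.0 < rho < 1.0:
            raise ValueError(f"AR1 autocorrelation must lie in (-1, 1), got {rho}")
        lags = np.abs(np.subtract.outer(np.arange(t), np.arange(t)))
        return variance * rho ** lags
    if structure == "UN1":
        variances = np.asarray(theta, dtype=float).ravel()
        if variances.shape != (t,):
            raise ValueError(
                f"UN1 residual needs {t} variances, got {variances.shape}"
            )
        if np.any(variances <= 0):
            raise ValueError("UN1 residual variances must all be > 0")
        return np.diag(variances)
    if structure == "UN":
        arr = np.asarray(theta, dtype=float)
        if arr.shape == (t, t):
            mat = 0.5 * (arr + arr.T)
        elif arr.ravel().shape == (t * (t + 1) // 2,):
            mat = np.zeros((t, t))
            idx = np.tril_indices(t)
            mat[idx] = arr.ravel()
            mat = mat + np.tril(mat, -1).T
        else:
            raise ValueError(
                f"UN residual needs a {t}x{t} matrix or its "
                f"{t * (t + 1) // 2} lower-triangle elements"
            )
        return mat
    raise ValueError(
        f"unknown residual structure {structure!r}; "
        f"expected one of {RESIDUAL_STRUCTURES}"
    )


@dataclass
class ParamVector:
    """Population or estimated parameters conforming to a :class:`ModelSpec`.

    Attributes
    ----------
    alpha
        Growth-factor means, length ``mean_order + 1``.
    psi
        Between-subject factor covariance (``r x r`` PSD) or ``None``
        when the spec carries no random effects.
    theta
        Residual parameters in the structure-specific form accepted by
        :func:`build_theta`.
    """

    alpha: np.ndarray
    psi: np.ndarray | None
    theta: object

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.psi is not None:
            self.psi = np.asarray(self.psi, dtype=float)
            if self.psi.size == 0:
                self.psi = None


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied mean vector and covariance matrix of the waves."""

    mu: np.ndarray
    sigma: np.ndarray


def _check_psd(mat: np.ndarray, name: str) -> None:
    smallest = float(np.linalg.eigvalsh(mat)[0])
    if smallest < -_PSD_TOL:
        raise ValueError(
            f"{name} matrix is not positive semi-definite "
            f"(smallest eigenvalue {smallest:.3e})"
        )


def implied_moments(spec: ModelSpec, params: ParamVector) -> ImpliedMoments:
    """First and second moments implied by ``params`` under ``spec``.

    ``mu = Lambda alpha`` and ``sigma = Lambda_r Psi Lambda_r' + Theta``;
    the Psi term is absent when the spec carries no random effects.
    """
    lam = polynomial_loadings(spec.n_waves, spec.mean_order)
    if params.alpha.shape != (spec.n_factors,):
        raise ValueError(
            f"alpha must have length {spec.n_factors}, "
            f"got {params.alpha.shape}"
        )
    mu = lam @ params.alpha
    theta = build_theta(spec.residual_structure, spec.n_waves, params.theta)
    _check_psd(theta, "theta")
    r = spec.n_random_effects
    if r > 0:
        psi = params.psi
        if psi is None or psi.shape != (r, r):
            raise ValueError(
                f"psi must be a {r}x{r} matrix under policy "
                f"{spec.random_effects_policy!r}"
            )
        _check_psd(psi, "psi")
        lam_r = lam[:, :r]
        sigma = lam_r @ psi @ lam_r.T + theta
    else:
        sigma = theta
    sigma = 0.5 * (sigma + sigma.T)
    return ImpliedMoments(mu=mu, sigma=sigma)
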