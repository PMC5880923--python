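"""Population models and synthetic-data generation for the simulation study.

Two true trajectories are emulated: a linear growth model observed at 4
waves and a quadratic growth model observed at 8 waves.  A single
standard-normal, time-invariant covariate ``w`` is regressed on every
growth factor with a common effect size ``gamma``; the within-subject
residual covariance follows one of three structures (ID, AR(1), UN(1));
sample sizes are 100, 210 and 390.  The full factorial design crosses
2 trajectories x 3 residual structures x 3 effect sizes x 3 sample sizes
= 54 cells.

Data generation follows the factor model

    w_i   ~ N(0, 1)
    eta_i = alpha + Gamma w_i + zeta_i,   zeta_i ~ N(0, Psi_zeta)
    y_i   = Lambda eta_i + eps_i,         eps_i  ~ N(0, Theta)

Under the default "standardized" reading of the effect size, ``gamma`` is
the covariate-factor correlation: ``Gamma_j = gamma * sqrt(Psi_total_jj)``
and ``Psi_zeta = Psi_total - Gamma Gamma'``, so the *total* factor
covariance equals the printed ``Psi_total`` for every gamma.  The "raw"
reading uses a constant coefficient ``Gamma_j = gamma`` on top of the
printed matrix, inflating the totals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import ImpliedMoments, build_theta, polynomial_loadings

__all__ = [
    "TRAJECTORIES",
    "POP_RESIDUAL_STRUCTURES",
    "GAMMAS",
    "SAMPLE_SIZES",
    "PSI_TOTAL_LINEAR",
    "PSI_TOTAL_QUADRATIC",
    "ALPHA_LINEAR",
    "ALPHA_QUADRATIC",
    "PopulationCondition",
    "Dataset",
    "DesignEntry",
    "theta_matrix",
    "psi_and_gamma",
    "population_moments",
    "generate_dataset",
    "enumerate_design",
    "seed_for",
]

#: trajectory name -> (number of waves, true polynomial order)
TRAJECTORIES = {"linear4": (4, 1), "quadratic8": (8, 2)}

POP_RESIDUAL_STRUCTURES = ("ID", "UN1", "AR1")
GAMMAS = (0.1, 0.3, 0.5)
SAMPLE_SIZES = (100, 210, 390)

# Total between-subject factor covariance matrices: intercept variance
# 0.20, growth-term variances 0.10, all pairwise factor correlations 0.35.
PSI_TOTAL_LINEAR = np.array([[0.20, 0.05], [0.05, 0.10]])
PSI_TOTAL_QUADRATIC = np.array(
    [
        [0.20, 0.05, 0.05],
        [0.05, 0.10, 0.035],
        [0.05, 0.035, 0.10],
    ]
)

# Default growth-factor means (medium-effect trajectories).
ALPHA_LINEAR = np.array([1.0, 0.5])
ALPHA_QUADRATIC = np.array([1.0, 0.5, 0.1])

_PSI_DEFAULTS = {"linear4": PSI_TOTAL_LINEAR, "quadratic8": PSI_TOTAL_QUADRATIC}
_ALPHA_DEFAULTS = {"linear4": ALPHA_LINEAR, "quadratic8": ALPHA_QUADRATIC}


def theta_matrix(
    structure: str,
    n_waves: int,
    variance: float = 1.0,
    rho: float = 0.5,
    first_variance: float = 1.0,
    decay: float = 0.8,
) -> np.ndarray:
    """Population within-subject residual covariance matrix.

    ID: ``variance * I``.  AR1: entries ``variance * rho**|i-j|`` with
    ``rho = 0.50`` by default.  UN1: zero covariances with wave-``j``
    variance ``first_variance * decay**(j-1)`` (defaults 1.00 and 0.80,
    i.e. 1.00, 0.80, 0.64, 0.51, ... — measurement reliability improving
    over time).
    """
    if structure == "ID":
        return build_theta("ID", n_waves, variance)
    if structure == "AR1":
        return build_theta("AR1", n_waves, (variance, rho))
    if structure == "UN1":
        if first_variance <= 0 or decay <= 0:
            raise ValueError("UN1 first variance and decay must be > 0")
        variances = first_variance * decay ** np.arange(n_waves)
        return build_theta("UN1", n_waves, variances)
    raise ValueError(
        f"unknown population residual structure {structure!r}; "
        f"expected one of {POP_RESIDUAL_STRUCTURES}"
    )


def psi_and_gamma(
    trajectory: str,
    gamma: float,
    interpretation: str = "standardized",
    psi_total: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the printed factor covariance into residual Psi and Gamma.

    Returns ``(Psi_zeta, Gamma)`` such that the total factor covariance is
    ``Psi_zeta + Gamma Gamma'``.  See the module docstring for the two
    readings of the effect size.
    """
    if trajectory not in TRAJECTORIES:
        raise ValueError(
            f"unknown trajectory {trajectory!r}; expected one of "
            f"{tuple(TRAJECTORIES)}"
        )
    psi_total = np.asarray(
        _PSI_DEFAULTS[trajectory] if psi_total is None else psi_total,
        dtype=float,
    )
    p = psi_total.shape[0]
    if interpretation == "standardized":
        if not -1.0 < gamma < 1.0:
            raise ValueError(
                f"standardized effect size must lie in (-1, 1), got {gamma}"
            )
        gam = gamma * np.sqrt(np.diag(psi_total))
        psi_zeta = psi_total - np.outer(gam, gam)
        if float(np.linalg.eigvalsh(psi_zeta)[0]) < -1e-10:
            raise ValueError(
                f"gamma={gamma} leaves a non-PSD residual factor "
                "covariance under the standardized interpretation"
            )
    elif interpretation == "raw":
        gam = np.full(p, float(gamma))
        psi_zeta = psi_total.copy()
    else:
        raise ValueError(
            f"unknown interpretation {interpretation!r}; "
            "expected 'standardized' or 'raw'"
        )
    return psi_zeta, gam


@dataclass(frozen=True)
class PopulationCondition:
    """One cell of the simulation design.

    ``alpha`` and ``psi_total`` default to the study values for the
    trajectory; override them for sensitivity analyses.
    """

    trajectory: str
    residual_structure: str
    gamma: float
    n: int
    alpha: np.ndarray | None = None
    psi_total: np.ndarray | None = None
    interpretation: str = "standardized"

    def __post_init__(self) -> None:
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(
                f"unknown trajectory {self.trajectory!r}; expected one of "
                f"{tuple(TRAJECTORIES)}"
            )
        if self.residual_structure not in POP_RESIDUAL_STRUCTURES:
            raise ValueError(
                f"unknown population residual structure "
                f"{self.residual_structure!r}; expected one of "
                f"{POP_RESIDUAL_STRUCTURES}"
            )
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        # freeze resolved defaults so downstream code never re-resolves
        object.__setattr__(
            self,
            "alpha",
            np.asarray(
                _ALPHA_DEFAULTS[self.trajectory]
                if self.alpha is None
                else self.alpha,
                dtype=float,
            ),
        )
        object.__setattr__(
            self,
            "psi_total",
            np.asarray(
                _PSI_DEFAULTS[self.trajectory]
                if self.psi_total is None
                else self.psi_total,
                dtype=float,
            ),
        )

    @property
    def n_waves(self) -> int:
        return TRAJECTORIES[self.trajectory][0]

    @property
    def true_order(self) -> int:
        return TRAJECTORIES[self.trajectory][1]

    @property
    def label(self) -> str:
        return (
            f"{self.trajectory},{self.residual_structure.lower()},"
            f"{self.gamma:g},{self.n}"
        )

    def theta(self) -> np.ndarray:
        return theta_matrix(self.residual_structure, self.n_waves)

    def split_psi(self) -> tuple[np.ndarray, np.ndarray]:
        return psi_and_gamma(
            self.trajectory, self.gamma, self.interpretation, self.psi_total
        )


@dataclass
class Dataset:
    """Complete wide-format data: outcomes ``y`` (n x t), covariate ``w``."""

    y: np.ndarray
    w: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be a 2-d (subjects x waves) array")
        if np.isnan(self.y).any():
            raise ValueError("y contains missing values")
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float).ravel()
            if self.w.shape != (self.y.shape[0],):
                raise ValueError("w length must match the number of subjects")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_waves(self) -> int:
        return self.y.shape[1]


def population_moments(cond: PopulationCondition) -> ImpliedMoments:
    """Marginal (over w) mean and covariance of y under the condition.

    ``mu = Lambda alpha`` since ``E(w) = 0``;
    ``sigma = Lambda (Psi_zeta + Gamma Gamma') Lambda' + Theta``.
    """
    lam = polynomial_loadings(cond.n_waves, cond.true_order)
    psi_zeta, gam = cond.split_psi()
    psi_marg = psi_zeta + np.outer(gam, gam)
    sigma = lam @ psi_marg @ lam.T + cond.theta()
    return ImpliedMoments(mu=lam @ cond.alpha, sigma=0.5 * (sigma + sigma.T))


def generate_dataset(cond: PopulationCondition, seed) -> Dataset:
    """Draw one complete dataset from the population model.

    Deterministic for a fixed seed (any value accepted by
    ``numpy.random.default_rng``).
    """
    rng = np.random.default_rng(seed)
    lam = polynomial_loadings(cond.n_waves, cond.true_order)
    psi_zeta, gam = cond.split_psi()
    theta = cond.theta()
    n, t, p = cond.n, cond.n_waves, cond.true_order + 1

    w = rng.standard_normal(n)
    # eigen-based square roots tolerate the PSD-but-singular gamma limits
    chol_psi = _psd_sqrt(psi_zeta)
    chol_theta = np.linalg.cholesky(theta)
    zeta = rng.standard_normal((n, p)) @ chol_psi.T
    eta = cond.alpha[None, :] + w[:, None] * gam[None, :] + zeta
    eps = rng.standard_normal((n, t)) @ chol_theta.T
    y = eta @ lam.T + eps
    meta = {"condition": cond.label, "seed": seed}
    return Dataset(y=y, w=w, meta=meta)


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


@dataclass(frozen=True)
class DesignEntry:
    """One dataset of the factorial design: condition, replicate, seed."""

    condition: PopulationCondition
    replicate: int
    seed: int
    cell_index: int


def _design_cells() -> list[tuple[str, str, float, int]]:
    return list(
        itertools.product(
            tuple(TRAJECTORIES), POP_RESIDUAL_STRUCTURES, GAMMAS, SAMPLE_SIZES
        )
    )


def seed_for(master_seed: int, cell_index: int, replicate: int) -> int:
    """Per-dataset seed from the master seed and the (cell, replicate) counter.

    Uses ``numpy.random.SeedSequence((master_seed, cell_index, replicate))``
    so any single dataset can be regenerated in isolation.
    """
    ss = np.random.SeedSequence((master_seed, cell_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def enumerate_design(
    reps: int,
    master_seed: int = 0,
    trajectories=None,
    residuals=None,
    gammas=None,
    sample_sizes=None,
) -> list[DesignEntry]:
    """Enumerate the factorial design with per-dataset seeds.

    The full grid has 54 cells; ``reps`` replicates per cell gives
    ``54 * reps`` entries (54,000 at the study's 1,000 replications).
    Optional keyword filters restrict the grid to subsets of each factor.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    entries = []
    for cell_index, (traj, resid, gamma, n) in enumerate(_design_cells()):
        if trajectories is not None and traj not in trajectories:
            continue
        if residuals is not None and resid not in residuals:
            continue
        if gammas is not None and gamma not in gammas:
            continue
        if sample_sizes is not None and n not in sample_sizes:
            continue
        cond = PopulationCondition(
            trajectory=traj, residual_structure=resid, gamma=gamma, n=n
        )
        for rep in range(reps):
            entries.append(
                DesignEntry(
                    condition=cond,
                    replicate=rep,
                    seed=seed_for(master_seed, cell_index, rep),
                    cell_index=cell_index,
                )
            )
    return entries
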