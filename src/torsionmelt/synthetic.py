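"""Synthetic ensembles standing in for MD output.

Everything the analysis modules consume can be generated here: Gaussian
helical-parameter trajectories under a known block-tridiagonal stiffness,
the same ensembles under a global twist restraint (with the analytic
restrained covariance available in closed form), the two-oscillator
demonstration of restraint-broken equipartition, bimodal BI/BII twist
mixtures, and the two reference 50-bp duplexes.

The default stiffness template is tuned so the implied twist persistence
length sits near 112 nm, inside the 100-120 nm range measured for B-DNA,
and marginal twist fluctuations of ~4-5 degrees per step — a realistic
regime for room-temperature duplex DNA.  All generators are reproducible
from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .constants import DEFAULT_TEMPERATURE, RISE_PER_STEP_NM, kbt
from .elastic import HelicalTrajectory
from .ising import IsingParameters
from .sequences import DuplexSequence

#: Reference 50-bp duplexes: a mixed ~50% A/T sequence and an otherwise
#: all-G/C sequence, both carrying the TATA box "ttatat" at bp 17-22 and
#: the torsionally active region between bp 4 and 47.
_AT_BASES = "cgcgcatgaactgcagttatatggacctcgatgcggcgtacagtacgcgc"
_GC_BASES = "cgcgcgcgcgcggccgttatatgggccgcgcggcggcgcgccgcgcgcgc"

#: Duplex twist persistence lengths (nm) measured for the two reference
#: sequences from unrestrained trajectories.
REFERENCE_P_TWIST: Mapping[str, float] = {"AT": 110.8, "GC": 119.9}


def reference_sequences() -> dict[str, DuplexSequence]:
    """The two packaged 50-bp duplex fixtures, keyed "AT" and "GC"."""
    return {
        "AT": DuplexSequence(_AT_BASES, melt_region=(17, 22), label="AT"),
        "GC": DuplexSequence(_GC_BASES, melt_region=(17, 22), label="GC"),
    }


def reference_parameters(label: str = "AT", **overrides) -> IsingParameters:
    """Default melting-model parameters for one of the packaged duplexes."""
    if label not in REFERENCE_P_TWIST:
        raise KeyError(f"unknown sequence label {label!r}; expected AT or GC")
    kwargs = {"p_twist": REFERENCE_P_TWIST[label]}
    kwargs.update(overrides)
    return IsingParameters(**kwargs)


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic helical-parameter ensemble.

    The stiffness template is block-tridiagonal: each step carries a
    diagonal 3x3 block diag(k_twist, k_roll, k_tilt) and couples to its
    neighbours through diag(g_twist, g_roll, g_tilt); units
    kcal mol^-1 deg^-2.  An optional global restraint acts on the total
    twist: either a soft harmonic ``restraint_k * (total - target)^2`` or
    a hard linear constraint ``total twist == target``.
    """

    n_steps: int = 43
    n_frames: int = 5000
    seed: int = 0
    mean_twist: float = 34.37
    mean_roll: float = 2.0
    mean_tilt: float = 0.0
    mean_rise: float = 3.4
    rise_sd: float = 0.1
    k_twist: float = 0.040
    k_roll: float = 0.020
    k_tilt: float = 0.035
    g_twist: float = 0.010
    g_roll: float = 0.005
    g_tilt: float = 0.005
    temperature: float = DEFAULT_TEMPERATURE
    restraint_k: float | None = None  # kcal/(mol deg^2) on the total twist
    target_total_twist: float | None = None  # degrees
    hard_constraint: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("need at least 2 steps")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.restraint_k is not None and self.restraint_k < 0:
            raise ValueError("restraint_k must be >= 0")

    @property
    def n_dof(self) -> int:
        return 3 * self.n_steps

    def mean_vector(self) -> np.ndarray:
        mu = np.empty(self.n_dof)
        mu[0::3] = self.mean_twist
        mu[1::3] = self.mean_roll
        mu[2::3] = self.mean_tilt
        return mu

    def stiffness_matrix(self) -> np.ndarray:
        """Assemble the block-tridiagonal stiffness (kcal/mol/deg^2)."""
        n = self.n_steps
        diag = np.array([self.k_twist, self.k_roll, self.k_tilt])
        off = np.array([self.g_twist, self.g_roll, self.g_tilt])
        k = np.zeros((self.n_dof, self.n_dof))
        for s in range(n):
            i = 3 * s
            k[i : i + 3, i : i + 3] = np.diag(diag)
            if s + 1 < n:
                j = i + 3
                k[i : i + 3, j : j + 3] = np.diag(off)
                k[j : j + 3, i : i + 3] = np.diag(off)
        evals = np.linalg.eigvalsh(k)
        if evals[0] <= 0:
            raise ValueError(
                f"stiffness template is not positive definite (min eig {evals[0]:.3e})"
            )
        return k

    def covariance_matrix(self) -> np.ndarray:
        """Equilibrium covariance kBT K^-1 (deg^2)."""
        return kbt(self.temperature) * np.linalg.inv(self.stiffness_matrix())

    def twist_selector(self) -> np.ndarray:
        """Vector a with a^T w = total twist (degrees)."""
        a = np.zeros(self.n_dof)
        a[0::3] = 1.0
        return a


def restrained_covariance(
    cov: np.ndarray,
    a: np.ndarray,
    restraint_k: float | None = None,
    hard: bool = False,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Covariance of a Gaussian under a global linear restraint.

    Hard constraint a^T x = const:  C' = C - C a a^T C / (a^T C a)
    (the conditional covariance; exactly one zero eigenvalue along a).
    Soft harmonic restraint k_R (a^T x - t)^2:
    C' = (C^-1 + 2 beta k_R a a^T)^-1, evaluated by the rank-one
    Sherman-Morrison update.  Either way the variance of a^T x shrinks.
    """
    cov = np.asarray(cov, dtype=float)
    a = np.asarray(a, dtype=float)
    if not np.any(a):
        raise ValueError("restraint direction a must be nonzero")
    ca = cov @ a
    denom = float(a @ ca)
    if denom <= 0:
        raise ValueError("a^T C a must be positive")
    if hard:
        return cov - np.outer(ca, ca) / denom
    if restraint_k is None:
        raise ValueError("provide restraint_k for a soft restraint, or hard=True")
    if restraint_k == 0:
        return cov.copy()
    g = 2.0 * restraint_k / kbt(temperature)
    return cov - np.outer(ca, ca) * (g / (1.0 + g * denom))


def _restrained_moments(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the restrained Gaussian ensemble."""
    cov = spec.covariance_matrix()
    mu = spec.mean_vector()
    a = spec.twist_selector()
    target = (
        spec.target_total_twist
        if spec.target_total_twist is not None
        else float(a @ mu)
    )
    if spec.hard_constraint:
        cov_r = restrained_covariance(cov, a, hard=True, temperature=spec.temperature)
        mu_r = mu + cov @ a * (target - a @ mu) / float(a @ cov @ a)
    else:
        if spec.restraint_k is None:
            raise ValueError("spec has no restraint; use sample_unrestrained")
        cov_r = restrained_covariance(
            cov, a, restraint_k=spec.restraint_k, temperature=spec.temperature
        )
        g = 2.0 * spec.restraint_k / kbt(spec.temperature)
        # posterior mean of the Gaussian tilted by the harmonic restraint
        prec = np.linalg.inv(cov)
        mu_r = np.linalg.solve(prec + g * np.outer(a, a), prec @ mu + g * target * a)
    return mu_r, cov_r


def _assemble_trajectory(
    spec: GeneratorSpec, dofs: np.ndarray, rng: np.random.Generator
) -> HelicalTrajectory:
    rise = rng.normal(spec.mean_rise, spec.rise_sd, size=(spec.n_frames, spec.n_steps))
    return HelicalTrajectory(
        twist=dofs[:, 0::3],
        roll=dofs[:, 1::3],
        tilt=dofs[:, 2::3],
        rise=rise,
        metadata={"spec": spec, "seed": spec.seed},
    )


def sample_unrestrained(spec: GeneratorSpec) -> HelicalTrajectory:
    """Draw frames from the unrestrained Gaussian kBT K^-1."""
    rng = np.random.default_rng(spec.seed)
    cov = spec.covariance_matrix()
    dofs = rng.multivariate_normal(
        spec.mean_vector(), cov, size=spec.n_frames, method="cholesky"
    )
    return _assemble_trajectory(spec, dofs, rng)


def sample_restrained(spec: GeneratorSpec) -> HelicalTrajectory:
    """Draw frames from the globally twist-restrained Gaussian.

    The restrained covariance couples distant steps (untwist somewhere
    must be compensated elsewhere to hold the total), which is what the
    long-range coupling score detects.
    """
    if spec.restraint_k is None and not spec.hard_constraint:
        raise ValueError("spec carries no restraint")
    mu_r, cov_r = _restrained_moments(spec)
    rng = np.random.default_rng(spec.seed)
    dofs = rng.multivariate_normal(mu_r, cov_r, size=spec.n_frames, method="svd")
    return _assemble_trajectory(spec, dofs, rng)


@dataclass(frozen=True)
class TwoOscillatorResult:
    """Analytic and sampled energy partition of the restrained dimer."""

    analytic_e1: float
    analytic_e2: float
    sampled_e1: float
    sampled_e2: float
    sampled_se1: float
    sampled_se2: float
    sampled_virial: np.ndarray  # <q_i dE/dq_i>, per coordinate
    kbt: float


def two_oscillator_demo(
    k1: float,
    k2: float,
    restraint_k: float = 0.0,
    l0: float = 0.0,
    n_frames: int = 50_000,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> TwoOscillatorResult:
    """Equipartition and its restraint-induced breakdown, exactly and by MC.

    Two uncoupled oscillators E_i = k_i q_i^2 share a global harmonic
    restraint k_R (q1 + q2 - L0)^2.  Unrestrained, <E1> = <E2> = kBT/2.
    Restrained with k1 != k2 the individual means differ, while the
    virial <q_i dE/dq_i> stays exactly kBT for each coordinate.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("oscillator constants must be positive")
    if restraint_k < 0:
        raise ValueError("restraint_k must be >= 0")
    kt = kbt(temperature)
    m = np.array([[k1 + restraint_k, restraint_k], [restraint_k, k2 + restraint_k]])
    cov = 0.5 * kt * np.linalg.inv(m)
    mu = restraint_k * l0 * np.linalg.solve(m, np.ones(2))
    e1 = k1 * (cov[0, 0] + mu[0] ** 2)
    e2 = k2 * (cov[1, 1] + mu[1] ** 2)
    rng = np.random.default_rng(seed)
    q = rng.multivariate_normal(mu, cov, size=n_frames, method="cholesky")
    s1 = k1 * q[:, 0] ** 2
    s2 = k2 * q[:, 1] ** 2
    resid = q.sum(axis=1) - l0
    virial = np.array(
        [
            np.mean(q[:, 0] * (2 * k1 * q[:, 0] + 2 * restraint_k * resid)),
            np.mean(q[:, 1] * (2 * k2 * q[:, 1] + 2 * restraint_k * resid)),
        ]
    )
    return TwoOscillatorResult(
        analytic_e1=float(e1),
        analytic_e2=float(e2),
        sampled_e1=float(s1.mean()),
        sampled_e2=float(s2.mean()),
        sampled_se1=float(s1.std(ddof=1) / np.sqrt(n_frames)),
        sampled_se2=float(s2.std(ddof=1) / np.sqrt(n_frames)),
        sampled_virial=virial,
        kbt=kt,
    )


def bimodal_twist(
    weights: tuple[float, float] = (0.65, 0.35),
    means: tuple[float, float] = (32.0, 38.0),
    sds: tuple[float, float] = (5.0, 3.0),
    n_frames: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-component twist mixture with substate labels (0 = BI, 1 = BII).

    Defaults encode the observed ordering for a CpG step: the BI substate
    twists less on average and fluctuates more than BII.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (2,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be two nonnegative numbers summing to 1")
    if np.any(np.asarray(sds) <= 0):
        raise ValueError("component standard deviations must be positive")
    rng = np.random.default_rng(seed)
    labels = rng.choice(2, p=w, size=n_frames)
    mu = np.asarray(means, dtype=float)[labels]
    sd = np.asarray(sds, dtype=float)[labels]
    return rng.normal(mu, sd), labels
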