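"""Harmonic elastic analysis of helical-parameter trajectories.

Near its equilibrium structure a DNA duplex behaves as a network of
coupled harmonic oscillators in the helical coordinates (twist, roll,
tilt per base-pair step).  The deformation energy of a frame is the
quadratic form ``E = 1/2 dw^T K dw`` with the stiffness matrix obtained
from the observed equilibrium fluctuations, ``K = kBT C^{-1}``.

Per-step energies use the half-split assignment: each degree of freedom
keeps its full diagonal term and half of every off-diagonal (coupling)
contribution, so the step energies sum exactly to the total quadratic
form, and for samples drawn from the model's own Gaussian each degree of
freedom carries kBT/2 on average (virial identity <dw_i (K dw)_i> = kBT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kbt

HELICAL_PARAMS = ("twist", "roll", "tilt")


@dataclass
class HelicalTrajectory:
    """Frames x steps series of twist/roll/tilt (degrees) and rise (A).

    Step indices are 1-based base-pair-step labels; ``values[param]`` is a
    (n_frames, n_steps) array.
    """

    twist: np.ndarray
    roll: np.ndarray
    tilt: np.ndarray
    rise: np.ndarray | None = None
    step_labels: Sequence[int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = {"twist": self.twist, "roll": self.roll, "tilt": self.tilt}
        shapes = {k: np.asarray(v).shape for k, v in arrays.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"angle arrays must share a shape, got {shapes}")
        for k, v in arrays.items():
            a = np.asarray(v, dtype=float)
            if a.ndim != 2:
                raise ValueError(f"{k} must be 2-D (frames x steps)")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{k} contains non-finite values")
            setattr(self, k, a)
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.n_steps < 2:
            raise ValueError("a trajectory needs at least 2 base-pair steps")
        if self.rise is not None:
            r = np.asarray(self.rise, dtype=float)
            if r.shape != self.twist.shape:
                raise ValueError("rise must match the angle arrays' shape")
            if not np.all(np.isfinite(r)):
                raise ValueError("rise contains non-finite values")
            self.rise = r
        if self.step_labels is None:
            self.step_labels = list(range(1, self.n_steps + 1))
        elif len(self.step_labels) != self.n_steps:
            raise ValueError("step_labels length must equal the step count")

    @property
    def n_frames(self) -> int:
        return self.twist.shape[0]

    @property
    def n_steps(self) -> int:
        return self.twist.shape[1]

    def dof_matrix(self) -> np.ndarray:
        """(n_frames, 3*n_steps) matrix, dofs grouped per step as
        (twist, roll, tilt) for step 1, then step 2, ..."""
        out = np.empty((self.n_frames, 3 * self.n_steps))
        out[:, 0::3] = self.twist
        out[:, 1::3] = self.roll
        out[:, 2::3] = self.tilt
        return out

    def dof_labels(self) -> list[str]:
        return [
            f"{param}:{label}"
            for label in self.step_labels
            for param in HELICAL_PARAMS
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, step, twist, roll, tilt[, rise]."""
        nf, ns = self.n_frames, self.n_steps
        data = {
            "frame": np.repeat(np.arange(nf), ns),
            "step": np.tile(np.asarray(self.step_labels), nf),
            "twist": self.twist.ravel(),
            "roll": self.roll.ravel(),
            "tilt": self.tilt.ravel(),
        }
        if self.rise is not None:
            data["rise"] = self.rise.ravel()
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StiffnessModel:
    """Mean vector, covariance and stiffness of the helical dofs.

    ``stiffness`` is in kcal mol^-1 deg^-2 and satisfies
    K C = kBT I by construction.
    """

    labels: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    stiffness: np.ndarray
    temperature: float

    @property
    def n_dof(self) -> int:
        return self.mean.size

    def energy(self, values: np.ndarray) -> np.ndarray:
        """Total deformation energy 1/2 dw^T K dw per frame (kcal/mol)."""
        dw = np.atleast_2d(values) - self.mean
        return 0.5 * np.einsum("fi,ij,fj->f", dw, self.stiffness, dw)


def fit_stiffness(
    traj: HelicalTrajectory,
    temperature: float = DEFAULT_TEMPERATURE,
    eig_floor: float = 1e-10,
) -> StiffnessModel:
    """Invert the sample covariance of the helical dofs: K = kBT C^{-1}.

    The covariance uses the unbiased (n-1) estimator.  Inversion goes
    through a symmetric eigendecomposition; an eigenvalue below
    ``eig_floor`` times the largest is reported as an error rather than
    silently regularized.
    """
    x = traj.dof_matrix()
    n_frames, n_dof = x.shape
    if n_frames < n_dof + 1:
        warnings.warn(
            f"{n_frames} frames for {n_dof} dofs: covariance is poorly "
            "conditioned below dim+1 frames",
            stacklevel=2,
        )
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= eig_floor * evals[-1]:
        i = int(np.argmin(evals))
        raise np.linalg.LinAlgError(
            f"covariance is singular: eigenvalue {evals[i]:.3e} "
            f"(mode {i}) below {eig_floor:.0e} of the largest {evals[-1]:.3e}"
        )
    inv = (evecs / evals) @ evecs.T
    stiffness = kbt(temperature) * inv
    return StiffnessModel(
        labels=tuple(traj.dof_labels()),
        mean=mean,
        covariance=cov,
        stiffness=stiffness,
        temperature=temperature,
    )


def half_split_dof_energy(model: StiffnessModel, values: np.ndarray) -> np.ndarray:
    """Per-dof energies 1/2 dw_i (K dw)_i (kcal/mol), frames x dofs.

    Each dof keeps its diagonal term plus half of every coupling term, so
    rows sum exactly to the total quadratic form.
    """
    dw = np.atleast_2d(values) - model.mean
    if dw.shape[1] != model.n_dof:
        raise ValueError(f"expected {model.n_dof} dofs, got {dw.shape[1]}")
    return 0.5 * dw * (dw @ model.stiffness)


def per_step_energy(model: StiffnessModel, values: np.ndarray) -> np.ndarray:
    """Per-base-pair-step energies (kcal/mol), frames x steps.

    Sums the half-split energies of the three helical dofs of each step.
    """
    e = half_split_dof_energy(model, values)
    if model.n_dof % 3:
        raise ValueError("model dofs are not grouped in (twist, roll, tilt) triples")
    return e.reshape(e.shape[0], -1, 3).sum(axis=2)


@dataclass(frozen=True)
class ElasticEnergySeries:
    """Per-frame/per-step elastic energies with profile summaries."""

    energies: np.ndarray  # frames x steps, kcal/mol
    step_labels: tuple[int, ...]
    mean_profile: np.ndarray
    smoothed_profile: np.ndarray  # 3-step running average, truncated at edges
    block_standard_errors: np.ndarray
    n_blocks: int


def elastic_energy_series(
    model: StiffnessModel,
    traj: HelicalTrajectory,
    window: int = 3,
    n_blocks: int = 20,
) -> ElasticEnergySeries:
    """Per-step energy profile with running averages and block errors.

    Standard errors split the frames into ``n_blocks`` contiguous blocks
    and take the standard error of the per-block means.
    """
    e = per_step_energy(model, traj.dof_matrix())
    mean = e.mean(axis=0)
    kernel = np.ones(window)
    smoothed = np.convolve(mean, kernel, mode="same") / np.convolve(
        np.ones_like(mean), kernel, mode="same"
    )
    blocks = np.array_split(e, n_blocks, axis=0)
    block_means = np.array([b.mean(axis=0) for b in blocks if b.size])
    se = block_means.std(axis=0, ddof=1) / np.sqrt(block_means.shape[0])
    return ElasticEnergySeries(
        energies=e,
        step_labels=tuple(traj.step_labels),
        mean_profile=mean,
        smoothed_profile=smoothed,
        block_standard_errors=se,
        n_blocks=len(block_means),
    )


def equipartition_report(
    traj: HelicalTrajectory, model: StiffnessModel
) -> pd.DataFrame:
    """Mean half-split energy per dof, in kBT units.

    For data drawn from the model's own Gaussian every entry is 1/2 in
    expectation; a global restraint redistributes energy between dofs and
    breaks this equality.
    """
    e = half_split_dof_energy(model, traj.dof_matrix())
    kt = kbt(model.temperature)
    mean = e.mean(axis=0) / kt
    se = e.std(axis=0, ddof=1) / np.sqrt(e.shape[0]) / kt
    return pd.DataFrame(
        {"dof": list(model.labels), "mean_energy_kbt": mean, "stderr_kbt": se}
    )


@dataclass(frozen=True)
class PersistenceEstimate:
    """Twist persistence length from cumulative-twist fluctuations."""

    contour_nm: float
    twist_variance_rad2: float

    @property
    def persistence_nm(self) -> float:
        return self.contour_nm / self.twist_variance_rad2


def twist_persistence_length(traj: HelicalTrajectory) -> PersistenceEstimate:
    """P = contour / Var(total twist), with the variance in rad^2.

    The contour is the frame-average of the summed per-step rises (A -> nm);
    the variance is that of the end-to-end cumulative twist, i.e. of the
    final base pair's orientation relative to the first.  Adding a
    constant to all twists leaves the estimate unchanged.
    """
    if traj.rise is None:
        raise ValueError("persistence length needs rise values")
    contour_nm = float(traj.rise.sum(axis=1).mean()) / 10.0
    total_twist = traj.twist.sum(axis=1)
    var = float(np.deg2rad(total_twist).var(ddof=1))
    if var == 0.0:
        raise ValueError("cumulative twist has zero variance")
    return PersistenceEstimate(contour_nm=contour_nm, twist_variance_rad2=var)


def twist_covariance_map(traj: HelicalTrajectory) -> np.ndarray:
    """Step x step covariance matrix of the twist fluctuations (deg^2)."""
    return np.atleast_2d(np.cov(traj.twist, rowvar=False, ddof=1))


def long_range_coupling_score(cov: np.ndarray) -> float:
    """Mean |correlation| outside the tridiagonal band, in [0, 1].

    Summarizes how much non-nearest-neighbour coupling a covariance map
    carries; torsionally relaxed DNA scores near zero, a globally
    twist-restrained ensemble scores higher.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance map must be symmetric")
    sd = np.sqrt(np.diag(cov))
    if np.any(sd == 0):
        return 0.0
    corr = cov / np.outer(sd, sd)
    n = corr.shape[0]
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mask = idx > 1
    if not mask.any():
        return 0.0
    return float(np.abs(corr[mask]).mean())
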