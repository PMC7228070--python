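"""Sequence-dependent single-bubble Ising model of torsion-induced DNA melting.

The duplex is a chain of two-state base pairs (intact / melted).  Under a
global untwist ``delta_tau`` (degrees) the system is either

* fully intact, storing the untwist as harmonic torsional strain of the
  duplex, ``H(n=0) = kBT * P / (2 L) * delta_tau^2`` (delta_tau in radians),
  with P the duplex twist persistence length and L its contour length; or
* carrying exactly one contiguous denaturation bubble of n melted base
  pairs, which costs a one-time initiation penalty epsilon, the lost
  pairing and stacking energies of the melted run, and absorbs the untwist
  with the much softer single-strand torsional stiffness C:
  ``E_bubble = C * (delta_tau - tau0*(n+1))^2 / (2 n)``.

Macrostates with more than one simultaneous bubble are excluded; for a
50-mer each extra bubble costs another epsilon = 4.1 kcal/mol, so their
weight is negligible.  The two terminal base pairs are boundary states
that never melt, so bubbles live strictly inside base pairs 2..N-1.

Each melted base pair is charged its pairing energy E_bp exactly once
(default).  ``pairing_double_count=True`` switches to the literal
nearest-neighbour interaction matrix in which every melted base pair is
charged once per adjacent step, i.e. twice in total; see docs/methods.md.

The partition sum is computed two independent ways: an explicit O(N^2)
enumeration of all single-bubble states (the reference), and a
melted-count-registered transfer (dynamic-programming) scan whose per-n
totals are re-weighted by the n-dependent bubble elastic factor.  Both run
in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import (
    DEFAULT_TAU0,
    DEFAULT_TEMPERATURE,
    RISE_PER_STEP_NM,
    kbt,
)
from .sequences import CANONICAL_STEPS, DuplexSequence, canonical_step

#: Empirical stacking free energies of the ten canonical base-pair steps,
#: kcal/mol (negative: stacking stabilizes the duplex).
DEFAULT_STACKING: dict[str, float] = {
    "ag": -1.44,
    "ac": -2.19,
    "at": -1.72,
    "aa": -1.49,
    "ta": -0.57,
    "tc": -1.81,
    "tg": -0.93,
    "gg": -1.82,
    "gc": -2.55,
    "cg": -1.29,
}

#: Pairing energies per base-pair class, kcal/mol.
DEFAULT_PAIRING: dict[str, float] = {"at": 0.64, "gc": 0.12}

#: Bubble initiation penalty, kcal/mol.
DEFAULT_EPSILON = 4.1

#: Torsional stiffness of a denaturation bubble, cal/(mol deg^2).
DEFAULT_C_BUBBLE = 0.79


@dataclass(frozen=True)
class IsingParameters:
    """All empirical constants of the melting model.

    Units: energies kcal/mol except ``c_bubble`` (cal mol^-1 deg^-2, the
    customary unit for single-strand torsional stiffness); lengths nm;
    angles degrees; temperature K.
    """

    stacking: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STACKING)
    )
    pairing: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PAIRING))
    epsilon: float = DEFAULT_EPSILON
    c_bubble: float = DEFAULT_C_BUBBLE
    tau0: float = DEFAULT_TAU0
    p_twist: float = 110.8
    contour_l: float | None = None
    temperature: float = DEFAULT_TEMPERATURE
    pairing_double_count: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in CANONICAL_STEPS if s not in self.stacking]
        if missing:
            raise ValueError(f"stacking table is missing canonical steps: {missing}")
        nonneg = {s: v for s, v in self.stacking.items() if v >= 0}
        if nonneg:
            raise ValueError(f"stacking energies must be negative: {nonneg}")
        for name, value in [
            ("epsilon", self.epsilon),
            ("c_bubble", self.c_bubble),
            ("tau0", self.tau0),
            ("p_twist", self.p_twist),
            ("temperature", self.temperature),
        ]:
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.contour_l is not None and not self.contour_l > 0:
            raise ValueError(f"contour_l must be positive, got {self.contour_l}")

    @property
    def beta(self) -> float:
        return 1.0 / kbt(self.temperature)

    def contour_for(self, seq: DuplexSequence) -> float:
        """Contour length (nm) of the torsionally active region."""
        if self.contour_l is not None:
            return self.contour_l
        return seq.n_active_steps * RISE_PER_STEP_NM

    def stacking_energy(self, step: str) -> float:
        """Stacking energy (kcal/mol) of a dinucleotide step."""
        key = canonical_step(step)
        try:
            return self.stacking[key]
        except KeyError:
            raise ValueError(f"no stacking energy configured for step {key!r}") from None

    def pairing_energy(self, base: str) -> float:
        """Pairing energy (kcal/mol) of the base pair containing ``base``."""
        base = base.lower()
        if base in "at":
            return self.pairing["at"]
        if base in "gc":
            return self.pairing["gc"]
        raise ValueError(f"invalid base {base!r}")


def stacking_energy(step: str, params: IsingParameters | None = None) -> float:
    """Module-level convenience wrapper around the parameter table."""
    return (params or IsingParameters()).stacking_energy(step)


def pairing_energy(base: str, params: IsingParameters | None = None) -> float:
    return (params or IsingParameters()).pairing_energy(base)


def bubble_elastic_energy(n: int, delta_tau: float, params: IsingParameters) -> float:
    """Torsional energy (kcal/mol) of an n-bp bubble absorbing the untwist.

    A bubble of n melted base pairs spans n+1 disrupted steps, each of
    which surrenders its equilibrium twist tau0; the residual twist
    mismatch is taken up at the soft single-strand stiffness C.
    """
    if n < 1:
        raise ValueError("bubble_elastic_energy requires n >= 1 (n=0 is the intact state)")
    if delta_tau < 0:
        raise ValueError("delta_tau must be >= 0")
    # c_bubble is cal/(mol deg^2); result in kcal/mol
    return params.c_bubble * 1e-3 * (delta_tau - params.tau0 * (n + 1)) ** 2 / (2.0 * n)


def intact_torsional_energy(
    delta_tau: float, params: IsingParameters, seq: DuplexSequence | None = None
) -> float:
    """Harmonic torsional energy (kcal/mol) of the fully intact duplex.

    ``kBT * P / (2 L) * delta_tau^2`` with delta_tau in radians; P/L is a
    dimensionless stiffness per squared radian.
    """
    if delta_tau < 0:
        raise ValueError("delta_tau must be >= 0")
    contour = params.contour_for(seq) if seq is not None else (
        params.contour_l if params.contour_l is not None else 43 * RISE_PER_STEP_NM
    )
    return (
        kbt(params.temperature)
        * params.p_twist
        / (2.0 * contour)
        * np.deg2rad(delta_tau) ** 2
    )


def _bubble_interval_ok(seq: DuplexSequence, start: int, n: int) -> None:
    end = start + n - 1
    if n < 1:
        raise ValueError("a bubble contains at least one melted base pair")
    if start < 2 or end > len(seq) - 1:
        raise ValueError(
            f"bubble {start}..{end} touches a terminal overhang base pair; "
            f"bubbles must lie inside 2..{len(seq) - 1}"
        )


def bubble_chain_energy(
    seq: DuplexSequence, start: int, n: int, params: IsingParameters
) -> float:
    """Pairing/stacking/initiation energy (kcal/mol) of one bubble state.

    Sums the nearest-neighbour interaction over every step touched by the
    melted run [start, start+n-1]: one epsilon at the intact->melted
    boundary, the lost stacking of the n+1 disrupted steps, and -E_bp per
    melted base pair (charged twice under ``pairing_double_count``).
    Excludes the torsional term.
    """
    _bubble_interval_ok(seq, start, n)
    end = start + n - 1
    mult = 2.0 if params.pairing_double_count else 1.0
    e = params.epsilon
    for i in range(start - 1, end + 1):  # steps (i, i+1) disrupted by the bubble
        e -= params.stacking_energy(seq.step(i))
    for i in range(start, end + 1):
        e -= mult * params.pairing_energy(seq.base(i))
    return e


def single_bubble_energy(
    seq: DuplexSequence,
    bubble_start: int,
    n: int,
    delta_tau: float,
    params: IsingParameters,
) -> float:
    """Total energy (kcal/mol) of the state with one bubble at a given place."""
    return bubble_chain_energy(seq, bubble_start, n, params) + bubble_elastic_energy(
        n, delta_tau, params
    )


def enumerate_bubble_states(
    seq: DuplexSequence,
    params: IsingParameters,
    allowed_region: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chain energies of every admissible single-bubble state.

    Returns arrays (start, n, chain_energy); the torsional terms are not
    included, so the result is independent of delta_tau and reusable
    across a sigma scan.
    """
    lo, hi = 2, len(seq) - 1
    if allowed_region is not None:
        rlo, rhi = allowed_region
        if rlo > rhi or rlo < 1 or rhi > len(seq):
            raise ValueError(f"allowed_region {allowed_region} outside the sequence")
        lo, hi = max(lo, rlo), min(hi, rhi)
    starts, lengths, energies = [], [], []
    for a in range(lo, hi + 1):
        # incremental extension keeps the scan O(N^2)
        e = params.epsilon - params.stacking_energy(seq.step(a - 1))
        mult = 2.0 if params.pairing_double_count else 1.0
        for b in range(a, hi + 1):
            e -= mult * params.pairing_energy(seq.base(b))
            e -= params.stacking_energy(seq.step(b))
            starts.append(a)
            lengths.append(b - a + 1)
            energies.append(e)
    return (
        np.array(starts, dtype=int),
        np.array(lengths, dtype=int),
        np.array(energies, dtype=float),
    )


def transfer_matrix_length_weights(
    seq: DuplexSequence,
    params: IsingParameters,
    allowed_region: tuple[int, int] | None = None,
) -> dict[int, float]:
    """log of the summed Boltzmann chain weights W(n), per bubble length n.

    A left-to-right transfer scan over base pairs with a melted-count
    register: states are (never melted), (inside a bubble, m melted so
    far) and (bubble closed, m melted).  Per-step factors are the
    Boltzmann factors of the nearest-neighbour interaction entries.
    Independent of delta_tau; re-weight by exp(-beta*E_bubble(n)) to
    assemble the partition sum.
    """
    n_bp = len(seq)
    beta = params.beta
    lo, hi = 2, n_bp - 1
    if allowed_region is not None:
        lo, hi = max(lo, allowed_region[0]), min(hi, allowed_region[1])
    extra = params.pairing_double_count  # extra -E_bp(i) charge on the melted-> side
    NEG = -np.inf
    in_bubble = np.full(n_bp + 2, NEG)  # index: melted count m
    closed = np.full(n_bp + 2, NEG)
    for i in range(2, n_bp + 1):  # base pair i enters at step (i-1, i)
        stack = params.stacking_energy(seq.step(i - 1))
        new_in = np.full_like(in_bubble, NEG)
        if lo <= i <= hi:
            ebp = params.pairing_energy(seq.base(i))
            # intact -> melted: epsilon - E_bp(i) - E_stack
            new_in[1] = -beta * (params.epsilon - ebp - stack)
            # melted -> melted: -E_bp(i) - E_stack (- E_bp(i-1) if double count)
            ext = -beta * (-ebp - stack)
            if extra:
                ext -= beta * (-params.pairing_energy(seq.base(i - 1)))
            new_in[2:] = in_bubble[1:-1] + ext
        # melted -> intact closes the bubble: -E_stack (- E_bp(i-1) if dc)
        close = -beta * (-stack)
        if extra:
            close -= beta * (-params.pairing_energy(seq.base(i - 1)))
        closed = np.logaddexp(closed, in_bubble + close)
        in_bubble = new_in
    # bp N is always intact, so every bubble has closed by now
    return {
        m: float(closed[m]) for m in range(1, n_bp + 2) if np.isfinite(closed[m])
    }


@dataclass(frozen=True)
class PartitionResult:
    """Boltzmann bookkeeping of the single-bubble ensemble at one untwist."""

    delta_tau: float
    log_z: float
    log_weight_intact: float
    starts: np.ndarray
    lengths: np.ndarray
    log_weights: np.ndarray
    n_bp: int

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    def free_energy_kcal(self, params: IsingParameters) -> float:
        """F = -kBT ln Z, kcal/mol (absolute, not referenced)."""
        return -kbt(params.temperature) * self.log_z

    @property
    def p_any_melt(self) -> float:
        """Probability that at least one base pair is melted."""
        return float(1.0 - np.exp(self.log_weight_intact - self.log_z))

    @property
    def p_melt(self) -> np.ndarray:
        """Per-base-pair melting probability, index 0 unused (1-based bps)."""
        p = np.zeros(self.n_bp + 1)
        w = np.exp(self.log_weights - self.log_z)
        for a, n, wi in zip(self.starts, self.lengths, w):
            p[a : a + n] += wi
        return p

    @property
    def p_bubble_length(self) -> np.ndarray:
        """Probability vector over bubble length n (index = n, n=0 intact)."""
        p = np.zeros(self.n_bp + 1)
        p[0] = np.exp(self.log_weight_intact - self.log_z)
        w = np.exp(self.log_weights - self.log_z)
        np.add.at(p, self.lengths, w)
        return p

    def weights_by_state(self) -> dict[tuple[int, int], float]:
        """(start, n) -> Boltzmann weight relative to exp(log_z - log_z)."""
        w = np.exp(self.log_weights)
        return {(int(a), int(n)): float(x) for a, n, x in zip(self.starts, self.lengths, w)}


def partition_function(
    seq: DuplexSequence,
    delta_tau: float,
    params: IsingParameters,
    allowed_region: tuple[int, int] | None = None,
    cross_check: bool = True,
    _chain: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> PartitionResult:
    """Partition sum and melting statistics at one value of the untwist.

    The state sum runs over the intact duplex plus every single contiguous
    bubble (optionally restricted to ``allowed_region``).  By default the
    enumeration total is verified against the independent transfer-scan
    route to a relative 1e-10; pass ``cross_check=False`` in tight loops.
    """
    if delta_tau < 0:
        raise ValueError("delta_tau must be >= 0")
    beta = params.beta
    starts, lengths, chain = (
        _chain if _chain is not None else enumerate_bubble_states(seq, params, allowed_region)
    )
    e_tors = np.array(
        [bubble_elastic_energy(int(n), delta_tau, params) for n in lengths]
    ) if len(lengths) else np.zeros(0)
    log_w = -beta * (chain + e_tors)
    log_w_intact = -beta * intact_torsional_energy(delta_tau, params, seq)
    log_z = logsumexp(np.concatenate([[log_w_intact], log_w]))
    if cross_check and len(lengths):
        log_wn = transfer_matrix_length_weights(seq, params, allowed_region)
        terms = [log_w_intact] + [
            lw - beta * bubble_elastic_energy(n, delta_tau, params)
            for n, lw in log_wn.items()
        ]
        log_z_tm = logsumexp(np.array(terms))
        if not np.isclose(log_z, log_z_tm, rtol=0, atol=1e-9):
            raise AssertionError(
                f"transfer-scan and enumeration disagree: {log_z} vs {log_z_tm}"
            )
    return PartitionResult(
        delta_tau=delta_tau,
        log_z=float(log_z),
        log_weight_intact=float(log_w_intact),
        starts=starts,
        lengths=lengths,
        log_weights=log_w,
        n_bp=len(seq),
    )


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energy vs supercoiling density, referenced to F(sigma=0)=0."""

    sigma: np.ndarray
    delta_tau: np.ndarray
    free_energy: np.ndarray
    p_any_melt: np.ndarray

    @property
    def melted_dominates(self) -> np.ndarray:
        return self.p_any_melt > 0.5


def _scan(
    seq: DuplexSequence,
    sigmas: np.ndarray,
    params: IsingParameters,
    allowed_region: tuple[int, int] | None = None,
):
    """Vectorized sigma scan reusing the delta_tau-independent chain energies."""
    chain = enumerate_bubble_states(seq, params, allowed_region)
    for s in sigmas:
        dtau = s * seq.n_active_steps * params.tau0
        yield partition_function(
            seq, dtau, params, allowed_region, cross_check=False, _chain=chain
        )


def free_energy_profile(
    seq: DuplexSequence,
    sigma_grid: Sequence[float],
    params: IsingParameters,
    allowed_region: tuple[int, int] | None = None,
) -> FreeEnergyProfile:
    """F(sigma) - F(0) along a nonnegative, increasing sigma grid."""
    sig = np.asarray(sigma_grid, dtype=float)
    if sig.size == 0:
        raise ValueError("sigma grid is empty")
    if np.any(sig < 0) or np.any(np.diff(sig) <= 0):
        raise ValueError("sigma grid must be nonnegative and strictly increasing")
    results = list(_scan(seq, sig, params, allowed_region))
    f = np.array([r.free_energy_kcal(params) for r in results])
    ref = (
        f[0]
        if sig[0] == 0.0
        else next(_scan(seq, np.array([0.0]), params, allowed_region)).free_energy_kcal(params)
    )
    return FreeEnergyProfile(
        sigma=sig,
        delta_tau=sig * seq.n_active_steps * params.tau0,
        free_energy=f - ref,
        p_any_melt=np.array([r.p_any_melt for r in results]),
    )


def melting_profile(
    seq: DuplexSequence, sigma: float, params: IsingParameters
) -> np.ndarray:
    """Per-base-pair melting probability at one supercoiling density."""
    dtau = sigma * seq.n_active_steps * params.tau0
    return partition_function(seq, dtau, params, cross_check=False).p_melt


def transition_sigma(
    seq: DuplexSequence,
    params: IsingParameters,
    sigma_max: float = 0.12,
    resolution: float = 0.001,
    region: tuple[int, int] | None = None,
) -> float | None:
    """Smallest grid sigma at which melted macrostates dominate.

    With ``region`` given, "melted" means a bubble overlapping that
    region (the local melting onset); otherwise any melted base pair
    counts.  Returns None when no grid point below sigma_max crosses 1/2.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    sigmas = np.arange(0.0, sigma_max + 0.5 * resolution, resolution)
    chain = enumerate_bubble_states(seq, params)
    starts, lengths, _ = chain
    if region is not None:
        rlo, rhi = region
        overlaps = ~((starts + lengths - 1 < rlo) | (starts > rhi))
    for s in sigmas:
        dtau = s * seq.n_active_steps * params.tau0
        r = partition_function(seq, dtau, params, cross_check=False, _chain=chain)
        if region is None:
            p = r.p_any_melt
        else:
            p = float(np.exp(logsumexp(r.log_weights[overlaps]) - r.log_z)) if overlaps.any() else 0.0
        if p > 0.5:
            return float(s)
    return None


def positional_entropy_effect(
    seq: DuplexSequence,
    region: tuple[int, int],
    sigma: float,
    params: IsingParameters,
) -> float:
    """Free-energy cost (kcal/mol) of pinning the bubble to one region.

    ``F_restricted - F_unrestricted = -kBT ln(Z_region / Z_full)``; always
    >= 0 because restricting the bubble's position removes states.  This
    quantifies how much positional freedom of the denaturation bubble is
    worth — the entropy an MD simulation forfeits when only the TATA box
    ever melts.
    """
    lo, hi = region
    if lo < 2 or hi > len(seq) - 1 or lo > hi:
        raise ValueError(f"region {region} must lie inside 2..{len(seq) - 1}")
    dtau = sigma * seq.n_active_steps * params.tau0
    z_full = partition_function(seq, dtau, params, cross_check=False)
    z_restricted = partition_function(
        seq, dtau, params, allowed_region=region, cross_check=False
    )
    return kbt(params.temperature) * (z_full.log_z - z_restricted.log_z)


def bubble_length_distribution(
    seq: DuplexSequence, sigma: float, params: IsingParameters
) -> np.ndarray:
    """Probability vector over bubble length n (index n; n=0 is intact)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    dtau = sigma * seq.n_active_steps * params.tau0
    return partition_function(seq, dtau, params, cross_check=False).p_bubble_length


def modal_bubble_length(
    seq: DuplexSequence, sigma: float, params: IsingParameters
) -> int:
    """Most probable melted length conditioned on at least one melted bp."""
    p = bubble_length_distribution(seq, sigma, params)
    return int(np.argmax(p[1:]) + 1)
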