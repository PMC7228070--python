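"""Duplex DNA sequences and the supercoiling-density coordinate.

A duplex is stored as its 5'->3' top strand; the bottom strand is implied
by Watson-Crick complementarity.  Base-pair indices are 1-based inclusive
everywhere, matching the usual "base pair 17" phrasing for the TATA box.
A base-pair *step* i is the junction between base pairs i and i+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

COMPLEMENT = {"a": "t", "t": "a", "g": "c", "c": "g"}

#: The ten dinucleotide-step representatives used for stacking energies.
#: The other six steps map onto these by reverse-complement symmetry
#: (a step read on the other strand is the same physical stack).
CANONICAL_STEPS = ("ag", "ac", "at", "aa", "ta", "tc", "tg", "gg", "gc", "cg")


def complement(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}; expected one of a,c,g,t") from None


def reverse_complement(seq: str) -> str:
    return "".join(complement(b) for b in reversed(seq))


def canonical_step(step: str) -> str:
    """Map a dinucleotide step to its strand-symmetric representative.

    Idempotent: canonical steps map to themselves.
    """
    if len(step) != 2:
        raise ValueError(f"a dinucleotide step has 2 bases, got {step!r}")
    step = step.lower()
    for b in step:
        if b not in COMPLEMENT:
            raise ValueError(f"invalid base {b!r} in step {step!r}")
    if step in CANONICAL_STEPS:
        return step
    rc = reverse_complement(step)
    if rc in CANONICAL_STEPS:
        return rc
    raise ValueError(f"step {step!r} has no canonical representative")


@dataclass(frozen=True)
class DuplexSequence:
    """A double-stranded DNA sequence with annotated regions.

    Parameters
    ----------
    bases
        Top strand, 5'->3', lower-case a/c/g/t.
    active_start, active_end
        1-based inclusive base pairs delimiting the torsionally active
        region (the part of the duplex that absorbs the imposed untwist).
        Default: three base pairs trimmed from each end (4..N-3, the
        torque-restraint anchoring used for the packaged 50-mers), or the
        whole duplex when it is too short to trim.
    melt_region
        Optional 1-based inclusive interval marking the melt-candidate
        region of interest (the TATA box for the packaged sequences).
    """

    bases: str
    active_start: int | None = None
    active_end: int | None = None
    melt_region: tuple[int, int] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        bases = self.bases.lower()
        object.__setattr__(self, "bases", bases)
        if len(bases) < 4:
            raise ValueError("duplex must be at least 4 bp long")
        bad = set(bases) - set("acgt")
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)}; only a,c,g,t allowed")
        n = len(bases)
        if self.active_start is None:
            object.__setattr__(self, "active_start", 4 if n >= 8 else 1)
        if self.active_end is None:
            object.__setattr__(self, "active_end", n - 3 if n >= 8 else n)
        if not (1 <= self.active_start < self.active_end <= n):
            raise ValueError(
                f"active region {self.active_start}..{self.active_end} "
                f"invalid for a {n}-bp duplex"
            )
        if self.melt_region is not None:
            lo, hi = self.melt_region
            if not (2 <= lo <= hi <= n - 1):
                raise ValueError(
                    f"melt_region {self.melt_region} must lie inside [2, {n - 1}]"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_active_steps(self) -> int:
        """Number of base-pair steps in the torsionally active region."""
        return self.active_end - self.active_start

    def base(self, i: int) -> str:
        """Base of the top strand at 1-based base pair i."""
        if not 1 <= i <= len(self.bases):
            raise IndexError(f"base pair {i} out of range 1..{len(self.bases)}")
        return self.bases[i - 1]

    def step(self, i: int) -> str:
        """Dinucleotide of step i (between base pairs i and i+1)."""
        if not 1 <= i <= len(self.bases) - 1:
            raise IndexError(f"step {i} out of range 1..{len(self.bases) - 1}")
        return self.bases[i - 1 : i + 1]

    def reverse_complement(self) -> "DuplexSequence":
        """The same physical duplex read from the other strand.

        Annotated regions are mirrored accordingly.
        """
        n = len(self.bases)
        mirror = lambda lo, hi: (n - hi + 1, n - lo + 1)
        mr = mirror(*self.melt_region) if self.melt_region else None
        a_lo, a_hi = mirror(self.active_start, self.active_end)
        return replace(
            self,
            bases=reverse_complement(self.bases),
            active_start=a_lo,
            active_end=a_hi,
            melt_region=mr,
        )


@dataclass(frozen=True)
class TorsionCoordinate:
    """Imposed global untwist and its supercoiling-density equivalent.

    sigma is the magnitude of fractional unwinding: imposed untwist
    divided by the equilibrium total twist of the active region,
    ``delta_tau = sigma * n_active_steps * tau0`` (degrees).
    """

    delta_tau: float
    sigma: float
    n_active_steps: int

    @classmethod
    def from_sigma(
        cls, sigma: float, n_active_steps: int, tau0: float
    ) -> "TorsionCoordinate":
        if sigma < 0:
            raise ValueError("sigma is a magnitude and must be >= 0")
        return cls(sigma * n_active_steps * tau0, sigma, n_active_steps)

    @classmethod
    def from_delta_tau(
        cls, delta_tau: float, n_active_steps: int, tau0: float
    ) -> "TorsionCoordinate":
        if delta_tau < 0:
            raise ValueError("delta_tau is a magnitude and must be >= 0")
        return cls(delta_tau, delta_tau / (n_active_steps * tau0), n_active_steps)


def sigma_to_delta_tau(sigma: float, n_active_steps: int = 43, tau0: float = 34.5) -> float:
    """Convert supercoiling density to total untwist in degrees."""
    return TorsionCoordinate.from_sigma(sigma, n_active_steps, tau0).delta_tau


def delta_tau_to_sigma(delta_tau: float, n_active_steps: int = 43, tau0: float = 34.5) -> float:
    """Convert total untwist in degrees to supercoiling density."""
    return TorsionCoordinate.from_delta_tau(delta_tau, n_active_steps, tau0).sigma
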