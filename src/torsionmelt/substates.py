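"""Backbone substates, base fraying and base-pair denaturation calls.

BI/BII: the phosphate backbone of B-DNA toggles between two substates
set by the epsilon/zeta dihedral combination — BI (epsilon/zeta in
trans/gauche-) and BII (gauche-/trans).  The standard scalar classifier
is the sign of the wrapped difference epsilon - zeta: negative -> BI,
non-negative -> BII (the threshold is configurable; no sharp boundary
exists in nature).

Fraying: a base is called frayed when it has swung away from the pairing
centre, detected by comparing the distance S (own sugar centre to the
base-pair centre point, the midpoint of the two sugar centres) with the
distance B (base reference atom, N1 for purines / N3 for pyrimidines, to
that centre point): frayed iff S < B.

Denaturation: a base pair is denatured when every Watson-Crick
donor-acceptor distance exceeds a cutoff (default 3.0 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BI = "BI"
BII = "BII"


def wrap_angle(angle: float | np.ndarray) -> np.ndarray:
    """Wrap an angle in degrees to [0, 360)."""
    return np.mod(angle, 360.0)


def _signed_difference(epsilon, zeta):
    """(epsilon - zeta) mod 360 mapped to (-180, 180]."""
    d = np.mod(np.asarray(epsilon, dtype=float) - np.asarray(zeta, dtype=float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def classify_bi_bii(epsilon, zeta, threshold: float = 0.0):
    """BI/BII label(s) from epsilon/zeta dihedrals (degrees).

    BI when the signed difference epsilon - zeta is below ``threshold``;
    BII otherwise (ties included).  Invariant to adding multiples of 360
    to either angle.  Accepts scalars or arrays.
    """
    d = _signed_difference(epsilon, zeta)
    labels = np.where(d < threshold, BI, BII)
    return labels.item() if labels.ndim == 0 else labels


@dataclass
class DihedralSeries:
    """Per-frame, per-nucleotide epsilon/zeta dihedrals (degrees).

    Arrays are (n_frames, n_nucleotides); values are wrapped to [0, 360).
    """

    epsilon: np.ndarray
    zeta: np.ndarray
    nucleotide_labels: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.epsilon = wrap_angle(np.atleast_2d(np.asarray(self.epsilon, dtype=float)))
        self.zeta = wrap_angle(np.atleast_2d(np.asarray(self.zeta, dtype=float)))
        if self.epsilon.shape != self.zeta.shape:
            raise ValueError("epsilon and zeta must have the same shape")
        if self.nucleotide_labels is None:
            self.nucleotide_labels = list(range(1, self.epsilon.shape[1] + 1))
        elif len(self.nucleotide_labels) != self.epsilon.shape[1]:
            raise ValueError("nucleotide_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return self.epsilon.shape[0]


def bi_fraction_profile(
    series: DihedralSeries,
    reference: DihedralSeries | None = None,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-nucleotide BI occupancy, optionally versus a reference ensemble.

    Returns columns nucleotide, bi_fraction and, when a reference is
    given, delta_bi (fraction minus the reference fraction); positive
    delta_bi means the backbone shifted toward BI.
    """
    if series.n_frames < 1:
        raise ValueError("need at least one frame")
    is_bi = classify_bi_bii(series.epsilon, series.zeta, threshold) == BI
    frac = is_bi.mean(axis=0)
    out = pd.DataFrame(
        {"nucleotide": list(series.nucleotide_labels), "bi_fraction": frac}
    )
    if reference is not None:
        if list(reference.nucleotide_labels) != list(series.nucleotide_labels):
            raise ValueError("series and reference cover different nucleotides")
        ref_bi = classify_bi_bii(reference.epsilon, reference.zeta, threshold) == BI
        out["delta_bi"] = frac - ref_bi.mean(axis=0)
    return out


#: Watson-Crick base reference atom per nucleobase: N1 for purines,
#: N3 for pyrimidines.
BASE_REFERENCE_ATOM: Mapping[str, str] = {"a": "N1", "g": "N1", "t": "N3", "c": "N3"}


@dataclass
class BasePairGeometry:
    """Toy per-frame geometry of one base pair, sufficient for fray calls.

    All coordinates are 3-vectors in A.  ``sugar_center`` / ``partner_sugar``
    may be pre-computed ring centroids, so no atomic structure is needed.
    """

    sugar_center: np.ndarray
    partner_sugar_center: np.ndarray
    base_reference: np.ndarray
    wc_distances: Sequence[float] | None = None

    def __post_init__(self) -> None:
        for name in ("sugar_center", "partner_sugar_center", "base_reference"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            setattr(self, name, v)


def sugar_ring_center(ring_atoms: np.ndarray) -> np.ndarray:
    """Centroid of the five sugar-ring atom positions (5x3 array, A)."""
    atoms = np.asarray(ring_atoms, dtype=float)
    if atoms.shape != (5, 3):
        raise ValueError("expected the five ring atoms as a 5x3 array")
    return atoms.mean(axis=0)


def fray_state(geometry: BasePairGeometry, own_sugar: bool = True) -> bool:
    """True when the base has swung away from the pairing centre.

    The centre point is the midpoint of the two sugar centres;
    S = |centre - sugar| (own sugar by default, the partner's with
    ``own_sugar=False``) and B = |centre - base reference|;
    frayed iff S < B.  Rigid rotations/translations leave the call
    unchanged.
    """
    center = 0.5 * (geometry.sugar_center + geometry.partner_sugar_center)
    sugar = geometry.sugar_center if own_sugar else geometry.partner_sugar_center
    s = float(np.linalg.norm(center - sugar))
    if np.allclose(geometry.sugar_center, geometry.partner_sugar_center):
        raise ValueError("degenerate geometry: coincident sugar centres")
    b = float(np.linalg.norm(center - geometry.base_reference))
    return s < b


def denatured(
    wc_distances: Sequence[float], cutoff: float = 3.0
) -> bool:
    """True when every Watson-Crick donor-acceptor distance exceeds cutoff.

    A single surviving hydrogen-bond contact keeps the pair intact;
    raising the cutoff can only clear the flag.
    """
    d = np.asarray(wc_distances, dtype=float)
    if d.size == 0:
        raise ValueError("no donor-acceptor distances given")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return bool(np.all(d > cutoff))


def denaturation_profile(
    wc_distance_series: np.ndarray, cutoff: float = 3.0
) -> np.ndarray:
    """Fraction of frames each base pair spends denatured.

    ``wc_distance_series`` is (n_frames, n_pairs, n_contacts); a frame
    counts as denatured for a pair when all its contacts exceed cutoff.
    """
    d = np.asarray(wc_distance_series, dtype=float)
    if d.ndim != 3:
        raise ValueError("expected a frames x pairs x contacts array")
    return np.all(d > cutoff, axis=2).mean(axis=0)
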