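"""Glycosidic torsions, Cremer-Pople ring puckering, and conformer regions.

Frames of a trajectory are reduced to a few periodic coordinates — the
glycosidic dihedral angles (phi1, phi2, and phi3 for 1->6 linkages) or the
puckering angles (theta, phi) of a six-membered ring — and assigned to
labeled conformer regions (free-energy-minimum neighborhoods) by nearest
center under the appropriate periodic metric.  Region populations are the
fractions of frames assigned to each label.

Ring atoms are ordered with the ring oxygen first (O5, C1..C5).  With the
sign conventions used here the 4C1 chair sits at theta = 0 and the 1C4
chair at theta = pi, matching the usual puckering-sphere convention for
pyranoses; skew-boats lie on the equator theta = pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "wrap_angle",
    "TorsionState",
    "RingPucker",
    "ConformerRegion",
    "dihedral",
    "cremer_pople",
    "assign_region",
    "region_populations",
]


def wrap_angle(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    y = -np.remainder(-np.asarray(x, dtype=float) + np.pi, 2 * np.pi) + np.pi
    return float(y) if np.isscalar(x) or np.ndim(x) == 0 else y


@dataclass(frozen=True)
class TorsionState:
    """Glycosidic torsion angles in radians, wrapped to (-pi, pi]."""

    phi1: float
    phi2: float
    phi3: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi1", wrap_angle(self.phi1))
        object.__setattr__(self, "phi2", wrap_angle(self.phi2))
        if self.phi3 is not None:
            object.__setattr__(self, "phi3", wrap_angle(self.phi3))

    @property
    def angles(self) -> tuple[float, ...]:
        return (self.phi1, self.phi2) if self.phi3 is None else (self.phi1, self.phi2, self.phi3)


@dataclass(frozen=True)
class RingPucker:
    """Cremer-Pople puckering of a six-membered ring.

    Total amplitude Q (Angstrom), polar angle theta in [0, pi] (0 = 4C1
    chair, pi = 1C4 chair, pi/2 = equatorial boats/skew-boats), azimuthal
    phase phi in [0, 2pi), and the Cartesian components
    (qx, qy, qz) = (Q sin(theta) cos(phi), Q sin(theta) sin(phi), Q cos(theta)).
    A planar ring has Q = 0 and undefined (NaN) angles.
    """

    Q: float
    theta: float
    phi: float

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.theta) and np.isfinite(self.phi))

    @property
    def qx(self) -> float:
        return self.Q * np.sin(self.theta) * np.cos(self.phi) if self.defined else 0.0

    @property
    def qy(self) -> float:
        return self.Q * np.sin(self.theta) * np.sin(self.phi) if self.defined else 0.0

    @property
    def qz(self) -> float:
        return self.Q * np.cos(self.theta) if self.defined else 0.0


@dataclass(frozen=True)
class ConformerRegion:
    """A labeled center in a periodic coordinate space.

    ``kind`` is "torsion" (center = torsion angles, wrapped Euclidean
    metric on the torus) or "pucker" (center = (phi, theta) on the
    puckering sphere, great-circle metric).  A ``None`` coordinate is a
    wildcard ("all"): it is ignored in the distance.
    """

    label: str
    center: tuple[float | None, ...]
    kind: str = "torsion"

    def __post_init__(self) -> None:
        if self.kind not in ("torsion", "pucker"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.kind == "pucker" and len(self.center) != 2:
            raise ValueError("pucker region center must be (phi, theta)")


def dihedral(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float], p4: Sequence[float]
) -> float:
    """Signed torsion angle p1-p2-p3-p4 in (-pi, pi], IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise ValueError("degenerate geometry: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: collinear triple")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    ang = float(np.arctan2(y, x))
    return np.pi if np.isclose(ang, -np.pi) else ang


def cremer_pople(ring_coords: np.ndarray) -> RingPucker:
    """Cremer-Pople puckering coordinates of six ordered ring atoms.

    ``ring_coords`` is (6, 3), atoms ordered around the ring starting at
    the ring oxygen (O5, C1..C5).  The mean plane is the standard
    Cremer-Pople plane (normal from the cross product of the two Fourier
    position sums); out-of-plane displacements z_j are decomposed into the
    m = 2 amplitude/phase (q2, phi2) and the alternating m = 3 amplitude
    q3, then mapped to (Q, theta, phi).
    """
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise ValueError(f"expected 6 ring atoms with 3 coordinates, got {r.shape}")
    r = r - r.mean(axis=0)
    j = np.arange(6)
    ang = 2.0 * np.pi * j / 6.0
    r_prime = (r * np.sin(ang)[:, None]).sum(axis=0)
    r_dprime = (r * np.cos(ang)[:, None]).sum(axis=0)
    n = np.cross(r_prime, r_dprime)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate ring geometry: undefined mean plane")
    n /= norm
    z = r @ n
    cos2 = np.cos(2.0 * ang)
    sin2 = np.sin(2.0 * ang)
    q2c = np.sqrt(1.0 / 3.0) * np.dot(z, cos2)
    q2s = -np.sqrt(1.0 / 3.0) * np.dot(z, sin2)
    q3 = np.sqrt(1.0 / 6.0) * np.dot(z, (-1.0) ** j)
    q2 = float(np.hypot(q2c, q2s))
    Q = float(np.sqrt(q2 * q2 + q3 * q3))
    if Q < 1e-10:
        return RingPucker(Q=Q, theta=float("nan"), phi=float("nan"))
    theta = float(np.arctan2(q2, q3))  # in [0, pi] since q2 >= 0
    phi = float(np.mod(np.arctan2(q2s, q2c), 2.0 * np.pi))
    return RingPucker(Q=Q, theta=theta, phi=phi)


# ---------------------------------------------------------------------------
# region assignment


def _torsion_distance(angles: tuple[float, ...], center: tuple[float | None, ...]) -> float:
    if len(angles) != len(center):
        raise ValueError("torsion state and region center dimensionality differ")
    d2 = 0.0
    for a, c in zip(angles, center):
        if c is None:
            continue
        d = wrap_angle(a - c)
        d2 += d * d
    return float(np.sqrt(d2))


def _pucker_distance(state: RingPucker, center: tuple[float | None, ...]) -> float:
    phi_c, theta_c = center
    if theta_c is None:
        raise ValueError("pucker region must fix theta")
    if not state.defined:
        raise ValueError("puckering angles undefined for a planar ring")
    if phi_c is None:
        return float(abs(state.theta - theta_c))
    # great-circle distance on the puckering sphere
    cosd = np.cos(state.theta) * np.cos(theta_c) + np.sin(state.theta) * np.sin(theta_c) * np.cos(
        state.phi - phi_c
    )
    return float(np.arccos(np.clip(cosd, -1.0, 1.0)))


def assign_region(
    state: TorsionState | RingPucker, regions: Sequence[ConformerRegion]
) -> tuple[str, float]:
    """Nearest region label and its periodic distance; ties go to the first listed."""
    if len(regions) == 0:
        raise ValueError("region list must be non-empty")
    if isinstance(state, TorsionState):
        kind = "torsion"
    elif isinstance(state, RingPucker):
        kind = "pucker"
    else:
        raise TypeError(f"cannot assign a {type(state).__name__}")
    best: tuple[str, float] | None = None
    for reg in regions:
        if reg.kind != kind:
            raise ValueError(f"region {reg.label!r} has kind {reg.kind!r}, state is {kind!r}")
        if kind == "torsion":
            d = _torsion_distance(state.angles, reg.center)
        else:
            d = _pucker_distance(state, reg.center)
        if best is None or d < best[1] - 1e-15:
            best = (reg.label, d)
    assert best is not None
    return best


def region_populations(
    states: Sequence[TorsionState] | Sequence[RingPucker],
    regions: Sequence[ConformerRegion],
) -> dict[str, float]:
    """Fraction of states assigned to each region label (all labels reported)."""
    if len(states) == 0:
        raise ValueError("need at least one state")
    if len(regions) == 0:
        raise ValueError("region list must be non-empty")
    counts = {reg.label: 0 for reg in regions}
    for s in states:
        lab, _ = assign_region(s, regions)
        counts[lab] += 1
    total = len(states)
    return {lab: c / total for lab, c in counts.items()}
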