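"""Nematic order statistics for sets of fiber orientations.

Stress fibers are axial objects: a fiber at angle ``theta`` is
indistinguishable from one at ``theta + 180``.  The standard way to quantify
the alignment of such a population is the 2D nematic order tensor.  Each
orientation ``theta_i`` is mapped to a unit vector ``p_i = (cos t, sin t)``
and the mean order tensor is

    T = < 2 p_i p_i^T - I >

(an average over fibers, optionally weighted).  T is symmetric and traceless,
so its eigenvalues are ``+lam`` and ``-lam``.  The orientational order
parameter (OOP) is the maximum eigenvalue ``lam``: 0 for an isotropic
population, 1 for perfect alignment.  The eigenvector of ``+lam`` is the
director, the dominant fiber orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AngleSet",
    "OrderTensor",
    "OOPResult",
    "order_tensor",
    "mean_order_tensor",
    "compute_oop",
    "oop_closed_form",
    "angular_histogram",
]


def fold_angle_deg(angles_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold angles into the nematic half-open interval [0, 180)."""
    return np.mod(angles_deg, 180.0)


@dataclass(frozen=True)
class AngleSet:
    """A set of fiber orientations in degrees, folded to [0, 180).

    ``weights`` are optional non-negative per-fiber weights (e.g. segment
    lengths); by default every fiber counts equally.
    """

    angles_deg: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if angles.ndim != 1:
            raise ValueError("angles_deg must be one-dimensional")
        if angles.size and not np.all(np.isfinite(angles)):
            raise ValueError("angles_deg must be finite")
        object.__setattr__(self, "angles_deg", fold_angle_deg(angles))
        if self.weights is not None:
            w = np.atleast_1d(np.asarray(self.weights, dtype=float))
            if w.shape != angles.shape:
                raise ValueError("weights must match angles_deg in length")
            if np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ValueError("weights must be finite and non-negative")
            if angles.size and not np.any(w > 0):
                raise ValueError("weights must not be all zero")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.angles_deg.size

    @classmethod
    def from_angles(
        cls, angles_deg: Sequence[float], weights: Sequence[float] | None = None
    ) -> "AngleSet":
        return cls(np.asarray(angles_deg, dtype=float),
                   None if weights is None else np.asarray(weights, dtype=float))


@dataclass(frozen=True)
class OrderTensor:
    """A symmetric 2x2 orientation tensor."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("order tensor must be 2x2")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("order tensor must be symmetric")
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class OOPResult:
    """Orientational order parameter of an angle set.

    ``director_deg`` is NaN when the population is perfectly isotropic
    (oop == 0), where no dominant direction exists.
    """

    oop: float
    director_deg: float
    n_angles: int
    length_weighted: bool = False

    @property
    def director_defined(self) -> bool:
        return np.isfinite(self.director_deg)


def order_tensor(angle_deg: float) -> OrderTensor:
    """Outer-product orientation tensor p p^T of a single angle."""
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    t = np.deg2rad(angle_deg)
    p = np.array([np.cos(t), np.sin(t)])
    return OrderTensor(np.outer(p, p))


def mean_order_tensor(angles: AngleSet) -> OrderTensor:
    """Weighted mean of 2 p_i p_i^T - I over the angle set (traceless)."""
    if len(angles) == 0:
        raise ValueError("cannot compute the mean order tensor of an empty angle set")
    t = np.deg2rad(angles.angles_deg)
    w = angles.weights
    # <2 pp^T - I> has entries <cos 2t> and <sin 2t>.
    c2 = np.average(np.cos(2 * t), weights=w)
    s2 = np.average(np.sin(2 * t), weights=w)
    return OrderTensor(np.array([[c2, s2], [s2, -c2]]))


def compute_oop(angles: AngleSet) -> OOPResult:
    """OOP and director: max eigenvalue/eigenvector of the mean order tensor."""
    tensor = mean_order_tensor(angles)
    eigvals, eigvecs = np.linalg.eigh(tensor.m)
    i_max = int(np.argmax(eigvals))
    oop = float(np.clip(eigvals[i_max], 0.0, 1.0))
    # below numerical noise the population is isotropic: no director exists
    if oop > 1e-12:
        v = eigvecs[:, i_max]
        director = float(fold_angle_deg(np.rad2deg(np.arctan2(v[1], v[0]))))
    else:
        director = float("nan")
    return OOPResult(
        oop=oop,
        director_deg=director,
        n_angles=len(angles),
        length_weighted=angles.weights is not None,
    )


def oop_closed_form(angles: AngleSet) -> float:
    """Closed-form OOP: sqrt(<cos 2t>^2 + <sin 2t>^2).

    Algebraically identical to the maximum eigenvalue of the traceless mean
    order tensor; kept as an independent route for cross-checking
    :func:`compute_oop`.
    """
    if len(angles) == 0:
        raise ValueError("cannot compute the OOP of an empty angle set")
    t = np.deg2rad(angles.angles_deg)
    w = angles.weights
    c2 = np.average(np.cos(2 * t), weights=w)
    s2 = np.average(np.sin(2 * t), weights=w)
    return float(np.hypot(c2, s2))


def angular_histogram(fs, bin_width_deg: float = 10.0):
    """Histogram of segment angles over [0, 180).

    Parameters
    ----------
    fs:
        A ``FilamentSet`` (anything with ``.segments`` each carrying
        ``angle_deg``) or an :class:`AngleSet`.
    bin_width_deg:
        Bin width in degrees; must divide 180 exactly.

    Returns
    -------
    (edges, counts):
        ``edges`` has ``n_bins + 1`` entries spanning [0, 180];
        ``counts`` sums to the number of segments.
    """
    n_bins = 180.0 / bin_width_deg
    if abs(n_bins - round(n_bins)) > 1e-9 or bin_width_deg <= 0:
        raise ValueError(
            f"bin_width_deg={bin_width_deg} does not divide 180 evenly"
        )
    n_bins = int(round(n_bins))
    if isinstance(fs, AngleSet):
        angles = fs.angles_deg
    else:
        angles = np.array([s.angle_deg for s in fs.segments], dtype=float)
    angles = fold_angle_deg(angles)
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return edges, counts
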