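"""Spine-budget arithmetic and density-driven spine placement.

A reduced compartmental MSN model that folds its spines into the dendritic
membrane (the Segev correction) over-reports the dendritic surface.  To make
the spines explicit again, this module inverts the correction: the surface
deficit between the corrected and the original dendrite is divided by the
exposed surface of one spine, giving the number of spines the tree must
carry.  Their placement follows a measured density profile of spine membrane
surface versus distance from the soma, fitted with a high-order polynomial
and discretized along each branch.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as _cheb


# ---------------------------------------------------------------------------
# spine section geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderSection:
    diameter: float  # um
    length: float    # um


@dataclass(frozen=True)
class SpineGeometry:
    """Three-section spine: post-synaptic density, head and neck cylinders."""

    psd: CylinderSection = CylinderSection(0.5, 0.05)
    head: CylinderSection = CylinderSection(1.175, 1.0)
    neck: CylinderSection = CylinderSection(0.1, 1.5)

    def head_volume_fl(self) -> float:
        """Head cylinder volume; 1 um^3 = 1 fL."""
        r = self.head.diameter / 2.0
        return math.pi * r * r * self.head.length


def cylinder_area(diameter: float, length: float, caps: bool = True) -> float:
    """Cylinder surface in um^2: lateral pi*d*L plus two end caps if caps."""
    if diameter < 0 or length < 0:
        raise ValueError("diameter and length must be >= 0")
    area = math.pi * diameter * length
    if caps:
        area += 2.0 * math.pi * (diameter / 2.0) ** 2
    return area


def spine_exposed_surface(geom: SpineGeometry | None = None) -> float:
    """Membrane surface one spine adds to the model, in um^2.

    The PSD is an internal section of the head, so only head and neck
    contribute.
    """
    geom = geom or SpineGeometry()
    return (cylinder_area(geom.head.diameter, geom.head.length)
            + cylinder_area(geom.neck.diameter, geom.neck.length))


def segev_fold(length: float, diameter: float, F: float) -> tuple[float, float]:
    """Fold spine membrane into a dendrite by rescaling its cylinder.

    ``F`` is the ratio (dendrite + spine area) / dendrite area.  The
    transform ``L' = L*F**(2/3)``, ``d' = d*F**(1/3)`` scales the lateral
    area by exactly F while keeping the L/d**(1/3) electrotonic relation.
    """
    if F < 1:
        raise ValueError("area ratio F must be >= 1")
    return length * F ** (2.0 / 3.0), diameter * F ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# spine budget
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineBudget:
    corrected_surface: float
    original_surface: float
    per_spine_surface: float
    deficit: float
    raw_count: int
    symmetrized_count: int
    per_branch_count: int
    n_dendrites: int
    final_count: int | None = None  # after proximal-noise removal, if known


def spine_budget(corrected: float, original: float, per_spine: float,
                 n_dendrites: int,
                 proximal_noise_per_branch: int = 0) -> SpineBudget:
    """Number of explicit spines implied by the folded-surface deficit.

    The raw count floors deficit/per_spine; it is then reduced to the
    largest multiple of ``n_dendrites`` so each primary dendrite carries the
    same number.  ``proximal_noise_per_branch`` spines per branch (artifacts
    of the density digitization placed over the soma and proximal
    dendrites) are removed from the final count.
    """
    if corrected <= original:
        raise ValueError("corrected surface must exceed the original")
    if per_spine <= 0:
        raise ValueError("per-spine surface must be > 0")
    if n_dendrites < 1:
        raise ValueError("need at least one dendrite")
    deficit = corrected - original
    raw = int(deficit / per_spine)
    symmetrized = (raw // n_dendrites) * n_dendrites
    per_branch = symmetrized // n_dendrites
    final = None
    if proximal_noise_per_branch:
        final = (per_branch - proximal_noise_per_branch) * n_dendrites
    return SpineBudget(
        corrected_surface=corrected, original_surface=original,
        per_spine_surface=per_spine, deficit=deficit, raw_count=raw,
        symmetrized_count=symmetrized,
        per_branch_count=per_branch,
        n_dendrites=n_dendrites, final_count=final)


# ---------------------------------------------------------------------------
# density profile
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Spine membrane surface per unit dendrite length vs distance from soma.

    The fit uses a Chebyshev basis over the sampled domain; a raw power
    basis is numerically unusable at order 17.  Evaluations are clamped at
    zero: a fitted density cannot go negative.
    """

    distances: np.ndarray          # um
    surface_density: np.ndarray    # um^2 per um
    order: int = 17
    _fit: _cheb.Chebyshev | None = field(default=None, repr=False)
    residual: float = field(default=float("nan"), repr=False)

    def fit(self) -> "DensityProfile":
        x = np.asarray(self.distances, dtype=float)
        y = np.asarray(self.surface_density, dtype=float)
        if x.size < self.order + 1:
            raise ValueError(
                f"need at least {self.order + 1} points for an order-"
                f"{self.order} fit, got {x.size}")
        self._fit = _cheb.Chebyshev.fit(x, y, deg=self.order)
        self.residual = float(np.sqrt(np.mean((self._fit(x) - y) ** 2)))
        return self

    def __call__(self, distance) -> np.ndarray:
        if self._fit is None:
            raise RuntimeError("profile not fitted; call fit() first")
        return np.clip(self._fit(np.asarray(distance, dtype=float)), 0.0, None)

    def integral(self, a: float, b: float, n: int = 2001) -> float:
        """Integral of the clamped density over [a, b] (composite Simpson)."""
        from scipy.integrate import simpson

        x = np.linspace(a, b, n)
        return float(simpson(self(x), x=x))


def fit_density(points, order: int = 17) -> DensityProfile:
    """Least-squares polynomial fit of (distance, surface-density) samples."""
    pts = np.asarray(points, dtype=float)
    return DensityProfile(distances=pts[:, 0], surface_density=pts[:, 1],
                          order=order).fit()


def load_profile_csv(path, order: int = 17) -> DensityProfile:
    """Fit a profile from a 2-column CSV (distance_um, surface_per_um)."""
    import pandas as pd

    df = pd.read_csv(path)
    return fit_density(df.iloc[:, :2].to_numpy(), order=order)


def placements_to_csv(placements, path) -> None:
    """Write spine placements as CSV (branch, position_um, spine_id)."""
    import pandas as pd

    pd.DataFrame([{"branch": p.segment, "position_um": p.position_um,
                   "spine_id": p.spine_id} for p in placements]).to_csv(
        path, index=False)


def synthetic_profile(n_points: int = 120, peak_um: float = 50.0,
                      peak_density: float = 30.0, extent_um: float = 220.0,
                      proximal_zero_um: float = 20.0, seed: int | None = None,
                      noise: float = 0.0, order: int = 17) -> DensityProfile:
    """Synthetic spine-surface density with the qualitative shape of MSN data.

    Near-zero over the proximal ``proximal_zero_um``, a peak around
    ``peak_um`` from the soma and a slow decay towards the distal tips.
    Optional Gaussian noise (relative amplitude ``noise``) takes an explicit
    seed.  This is a synthetic stand-in for digitized microscopy data, which
    are not shipped.
    """
    x = np.linspace(0.0, extent_um, n_points)
    rise = 1.0 / (1.0 + np.exp(-(x - proximal_zero_um - 12.0) / 5.0))
    decay = np.exp(-np.clip(x - peak_um, 0.0, None) / 130.0)
    y = peak_density * rise * decay
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y * (1.0 + noise * rng.standard_normal(y.shape)), 0.0, None)
    return DensityProfile(distances=x, surface_density=y, order=order).fit()


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchSegment:
    name: str
    start_um: float   # path distance from soma at segment start
    length_um: float


@dataclass(frozen=True)
class SpinePlacement:
    spine_id: str
    segment: str
    position_um: float  # path distance from soma


def distribute_spines(profile: DensityProfile,
                      branch_path: list[BranchSegment],
                      per_spine: float,
                      exclusion_um: float = 0.0,
                      share: int = 4) -> list[SpinePlacement]:
    """Place spines along one dendritic path from a fitted density profile.

    The fitted surface density is integrated along each segment, divided by
    ``share`` (the per-dendrite share of the whole-tree profile) and
    discretized into a spine count by the per-spine equivalent area.  Spines
    inside the proximal ``exclusion_um`` are removed.  Placement is
    deterministic: spines are evenly spaced within each segment.
    """
    if per_spine <= 0:
        raise ValueError("per-spine surface must be > 0")
    if exclusion_um < 0:
        raise ValueError("exclusion cutoff must be >= 0")
    placements: list[SpinePlacement] = []
    carry = 0.0  # fractional spine area carried between segments
    idx = 0
    for seg in branch_path:
        a, b = seg.start_um, seg.start_um + seg.length_um
        area = profile.integral(a, b) / share + carry
        n = int(area / per_spine)
        carry = area - n * per_spine
        if n == 0:
            continue
        # even spacing: centers of n equal sub-intervals
        positions = a + (np.arange(n) + 0.5) * seg.length_um / n
        for pos in positions:
            if pos < exclusion_um:
                continue
            placements.append(SpinePlacement(
                spine_id=f"spine{idx}", segment=seg.name,
                position_um=float(pos)))
            idx += 1
    return placements
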