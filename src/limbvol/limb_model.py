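"""Parametric synthetic limbs with closed-form ground-truth volumes.

Every downstream stage (tape volumetry, the scan pipeline, screening, the
agreement statistics) is tested against limbs generated here, so no patient
data is needed.  A limb is a surface of revolution: a piecewise-linear
radius profile ``r(s)`` along the axial coordinate ``s`` from the wrist
(ulnar styloid, ``s = 0``) to the axilla (``s = length_cm``).  Because the
profile is piecewise linear, the analytic volume ``pi * integral r(s)^2 ds``
is an exact sum of conical frusta — the same closed form the truncated-cone
method integrates — which makes ground truth exact rather than numeric.

Swelling is a multiplicative radial factor ``gamma >= 1`` applied uniformly
or over a sub-interval; uniform swelling scales the volume by exactly
``gamma**2``, the law the percent-difference screen should recover.

Conventions
-----------
World frame: ``+z`` up, ``+y`` anterior, ``+x`` the patient's left; the
trunk-down direction is ``-z``.  The limb's own axis is ``+z`` before pose
rotation; a pose is ``(abduction_deg, flexion_deg)`` — abduction tilts the
arm away from the trunk within the coronal (x–z) plane, flexion tilts it
anteriorly out of that plane.  Capture views are simulated by half-space
visibility: each of the four sensors (front, back, left, right) sees the
points whose outward surface normal faces it; the merged cloud assumes
perfect registration.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyScanError,
    InsufficientStationsError,
    InvalidParameterError,
    InvalidViewError,
)
from .geometry import CircumferenceSeries
from .scan_pipeline import LimbScan

__all__ = [
    "VIEW_ORDER",
    "VIEW_DIRECTIONS",
    "SyntheticLimb",
    "NoiseSpec",
    "make_limb",
    "sample_point_cloud",
    "simulate_tape_series",
    "random_limb",
    "pose_rotation",
]

VIEW_ORDER: tuple[str, ...] = ("front", "back", "left", "right")

#: Sensor directions in the world frame: the "front" sensor faces the
#: patient's anterior (+y) surface, and so on.
VIEW_DIRECTIONS: dict[str, np.ndarray] = {
    "front": np.array([0.0, 1.0, 0.0]),
    "back": np.array([0.0, -1.0, 0.0]),
    "left": np.array([1.0, 0.0, 0.0]),
    "right": np.array([-1.0, 0.0, 0.0]),
}


def pose_rotation(abduction_deg: float, flexion_deg: float) -> np.ndarray:
    """Rotation matrix taking the canonical limb frame into the world frame.

    At ``(0, 0)`` the arm hangs straight down (wrist below the axilla, limb
    axis ``+z``); abduction rotates it laterally in the coronal plane and
    flexion tilts it anteriorly.
    """
    a = np.radians(abduction_deg)
    f = np.radians(flexion_deg)
    ca, sa = np.cos(a), np.sin(a)
    cf, sf = np.cos(f), np.sin(f)
    rot_x = np.array([[1, 0, 0], [0, cf, -sf], [0, sf, cf]])
    rot_y = np.array([[ca, 0, -sa], [0, 1, 0], [sa, 0, ca]])  # R_y(-abduction)
    return rot_y @ rot_x


@dataclass(frozen=True)
class SyntheticLimb:
    """A ground-truth limb: radius profile, swelling, pose and RNG seed.

    ``knots`` are ``(s, r)`` pairs in cm with ``0 <= s <= length_cm``
    strictly increasing and ``r > 0``; the profile is linear between knots
    and constant beyond the first/last knot.  ``swelling_interval`` limits
    the radial inflation to ``lo <= s <= hi`` (inclusive); ``None`` means
    the whole limb.
    """

    length_cm: float
    knots: tuple[tuple[float, float], ...]
    swelling_factor: float = 1.0
    swelling_interval: tuple[float, float] | None = None
    pose: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def base_radius(self, s) -> np.ndarray:
        """Radius profile before swelling (constant extrapolation at ends)."""
        xs = np.array([k[0] for k in self.knots])
        rs = np.array([k[1] for k in self.knots])
        return np.interp(np.asarray(s, dtype=float), xs, rs)

    def effective_radius(self, s) -> np.ndarray:
        """Radius with the swelling factor applied."""
        s = np.asarray(s, dtype=float)
        r = self.base_radius(s)
        if self.swelling_factor == 1.0:
            return r
        if self.swelling_interval is None:
            return self.swelling_factor * r
        lo, hi = self.swelling_interval
        return np.where((s >= lo) & (s <= hi), self.swelling_factor * r, r)

    def _effective_pieces(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Continuous piecewise-linear pieces of the effective profile.

        A sub-interval swelling introduces jumps at its boundaries; each
        returned piece is (station array, radius array) linear between
        entries, so the volume integral is an exact frustum sum per piece.
        """
        breaks = {0.0, float(self.length_cm)}
        breaks.update(float(k[0]) for k in self.knots if 0 < k[0] < self.length_cm)
        if self.swelling_interval is not None and self.swelling_factor != 1.0:
            lo, hi = self.swelling_interval
            breaks.update(b for b in (lo, hi) if 0 < b < self.length_cm)
        xs = np.array(sorted(breaks))
        pieces = []
        for x0, x1 in zip(xs[:-1], xs[1:]):
            mid = 0.5 * (x0 + x1)
            gamma = float(self.effective_radius(mid) / self.base_radius(mid))
            pieces.append(
                (np.array([x0, x1]), gamma * self.base_radius(np.array([x0, x1])))
            )
        return pieces

    def analytic_volume(self) -> float:
        """Exact volume ``pi * integral r_eff(s)^2 ds`` in cm^3."""
        total = 0.0
        for xs, rs in self._effective_pieces():
            h = xs[1] - xs[0]
            r1, r2 = rs
            total += np.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
        return float(total)

    def rotation(self) -> np.ndarray:
        return pose_rotation(*self.pose)

    def landmarks(self) -> tuple[np.ndarray, np.ndarray]:
        """World-frame (wrist, axilla) positions; the wrist sits at the origin."""
        R = self.rotation()
        return np.zeros(3), R @ np.array([0.0, 0.0, self.length_cm])


@dataclass(frozen=True)
class NoiseSpec:
    """Imperfections applied when simulating a capture.

    Parameters
    ----------
    surface_sigma_cm
        Isotropic Gaussian jitter added to every surface point.
    points_per_view
        Points drawn per capture view before visibility culling.
    views
        Which of the four sensors captured (default all).
    occlusion_fraction
        Fraction of the proximal (axilla-side) limb with all points removed,
        emulating clothing covering the upper arm.
    tape_sigma_cm
        Gaussian noise on simulated tape circumferences.
    """

    surface_sigma_cm: float = 0.0
    points_per_view: int = 5000
    views: tuple[str, ...] = VIEW_ORDER
    occlusion_fraction: float = 0.0
    tape_sigma_cm: float = 0.0

    def __post_init__(self) -> None:
        if self.surface_sigma_cm < 0 or self.tape_sigma_cm < 0:
            raise InvalidParameterError("noise sigmas must be >= 0")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise InvalidParameterError("occlusion_fraction must be in [0, 1]")
        if self.points_per_view < 0:
            raise InvalidParameterError("points_per_view must be >= 0")
        views = tuple(self.views)
        for v in views:
            if v not in VIEW_DIRECTIONS:
                raise InvalidViewError(f"unknown view {v!r}")
        if not views:
            raise InvalidParameterError("at least one view is required")
        object.__setattr__(self, "views", views)


def _normalize_knots(
    length_cm: float, radius_knots
) -> tuple[tuple[float, float], ...]:
    if np.isscalar(radius_knots):
        knots = [(0.0, float(radius_knots)), (float(length_cm), float(radius_knots))]
    elif isinstance(radius_knots, dict):
        knots = sorted((float(s), float(r)) for s, r in radius_knots.items())
    else:
        knots = sorted((float(s), float(r)) for s, r in radius_knots)
    if not knots:
        raise InvalidParameterError("radius_knots must not be empty")
    ss = [k[0] for k in knots]
    if any(s2 <= s1 for s1, s2 in zip(ss[:-1], ss[1:])):
        raise InvalidParameterError("knot stations must be strictly increasing")
    if ss[0] < 0 or ss[-1] > length_cm + 1e-9:
        raise InvalidParameterError("knot stations must lie within [0, length_cm]")
    if any(k[1] <= 0 for k in knots):
        raise InvalidParameterError("knot radii must be positive")
    # constant extension to the ends so r(s) is defined on the whole limb
    if knots[0][0] > 0:
        knots.insert(0, (0.0, knots[0][1]))
    if knots[-1][0] < length_cm:
        knots.append((float(length_cm), knots[-1][1]))
    return tuple(knots)


def make_limb(
    length_cm: float,
    radius_knots,
    swelling_factor: float = 1.0,
    pose: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    swelling_interval: tuple[float, float] | None = None,
) -> SyntheticLimb:
    """Build a :class:`SyntheticLimb` from a radius profile.

    ``radius_knots`` may be a scalar (a cylinder), a ``{s: r}`` mapping, or a
    sequence of ``(s, r)`` pairs.  ``swelling_factor`` must be >= 1 and the
    optional ``swelling_interval`` must lie within the limb.
    """
    if not np.isfinite(length_cm) or length_cm <= 0:
        raise InvalidParameterError(f"length_cm must be positive, got {length_cm}")
    if swelling_factor < 1.0:
        raise InvalidParameterError("swelling_factor must be >= 1")
    if swelling_interval is not None:
        lo, hi = swelling_interval
        if not (0.0 <= lo < hi <= length_cm):
            raise InvalidParameterError(
                "swelling_interval must satisfy 0 <= lo < hi <= length_cm"
            )
        swelling_interval = (float(lo), float(hi))
    return SyntheticLimb(
        length_cm=float(length_cm),
        knots=_normalize_knots(length_cm, radius_knots),
        swelling_factor=float(swelling_factor),
        swelling_interval=swelling_interval,
        pose=(float(pose[0]), float(pose[1])),
        seed=int(seed),
    )


def sample_point_cloud(
    limb: SyntheticLimb,
    noise: NoiseSpec | None = None,
    include_hand: bool = False,
    seed: int | None = None,
    patient_ref: str | None = None,
) -> LimbScan:
    """Simulate a multi-view capture of a limb.

    For each requested view, points are drawn uniformly in axial position
    and azimuth on the limb surface and kept when their outward normal faces
    that view's sensor (half-space visibility); clothing occlusion removes
    the proximal ``occlusion_fraction`` of the limb, and Gaussian surface
    jitter is added last.  ``include_hand`` appends a spherical blob distal
    to the wrist landmark to exercise the hand-sparing contract.  Fully
    deterministic for a fixed seed (``limb.seed`` unless overridden).
    """
    noise = noise or NoiseSpec()
    if noise.points_per_view == 0:
        raise EmptyScanError("points_per_view must be positive to capture a scan")
    rng = np.random.default_rng(limb.seed if seed is None else seed)
    R = limb.rotation()
    L = limb.length_cm
    s_max = (1.0 - noise.occlusion_fraction) * L

    clouds: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for view in noise.views:
        sensor = VIEW_DIRECTIONS[view]
        s = rng.uniform(0.0, L, noise.points_per_view)
        theta = rng.uniform(0.0, 2.0 * np.pi, noise.points_per_view)
        r = limb.effective_radius(s)
        canonical = np.column_stack((r * np.cos(theta), r * np.sin(theta), s))
        normals = np.column_stack(
            (np.cos(theta), np.sin(theta), np.zeros_like(theta))
        )
        world = canonical @ R.T
        visible = (normals @ R.T) @ sensor > 0.0
        keep = visible & (s <= s_max)
        pts = world[keep]
        if noise.surface_sigma_cm > 0:
            pts = pts + rng.normal(0.0, noise.surface_sigma_cm, pts.shape)
        clouds.append(pts)
        labels.append(np.full(pts.shape[0], VIEW_ORDER.index(view), dtype=int))

    if include_hand:
        r0 = float(limb.effective_radius(0.0))
        blob_r = 1.3 * r0
        center = np.array([0.0, 0.0, -(blob_r + 1.0)])
        n_hand = max(200, sum(c.shape[0] for c in clouds) // 10)
        dirs = rng.normal(size=(n_hand, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        hand = (center + blob_r * dirs) @ R.T
        if noise.surface_sigma_cm > 0:
            hand = hand + rng.normal(0.0, noise.surface_sigma_cm, hand.shape)
        clouds.append(hand)
        labels.append(np.full(n_hand, -1, dtype=int))

    points = np.vstack(clouds)
    if points.shape[0] == 0:
        raise EmptyScanError("no points survived visibility/occlusion culling")
    wrist, axilla = limb.landmarks()
    return LimbScan(
        points=points,
        view_labels=np.concatenate(labels),
        wrist_landmark=wrist,
        axilla_landmark=axilla,
        patient_ref=patient_ref,
    )


def simulate_tape_series(
    limb: SyntheticLimb,
    interval_cm: float = 4.0,
    tape_sigma_cm: float = 0.0,
    seed: int | None = None,
    side: str | None = None,
    include_partial_end: bool = True,
) -> CircumferenceSeries:
    """Simulate tape measurements every ``interval_cm`` from wrist to axilla.

    Stations sit at ``0, interval, 2*interval, ...`` up to the limb length;
    when the length is not a station multiple a final station at the axilla
    is added (``include_partial_end``) so the trailing partial segment is
    measured rather than discarded.  The noiseless circumference at station
    ``s`` is ``2*pi*r_eff(s)``.  Gaussian tape noise is floored at 0.1 cm so
    a simulated reading can never be non-physical.
    """
    if interval_cm <= 0:
        raise InvalidParameterError("interval_cm must be positive")
    if interval_cm > limb.length_cm:
        raise InsufficientStationsError(
            f"interval {interval_cm} cm leaves a single grid station on a "
            f"{limb.length_cm} cm limb; volume needs >= 2"
        )
    stations = np.arange(0.0, limb.length_cm + 1e-9, interval_cm)
    if include_partial_end and limb.length_cm - stations[-1] > 1e-6:
        stations = np.append(stations, limb.length_cm)
    circs = 2.0 * np.pi * limb.effective_radius(stations)
    if tape_sigma_cm > 0:
        rng = np.random.default_rng(limb.seed if seed is None else seed)
        circs = circs + rng.normal(0.0, tape_sigma_cm, circs.shape)
        circs = np.maximum(circs, 0.1)
    return CircumferenceSeries(stations=stations, circumferences=circs, side=side)


def random_limb(
    rng: np.random.Generator,
    swelling_factor: float = 1.0,
    pose: tuple[float, float] = (0.0, 0.0),
    grid_cm: float | None = None,
) -> SyntheticLimb:
    """Draw a plausible adult arm for cohort simulations.

    Lengths 34–46 cm wrist to axilla with radii tapering from ~2.2–3.2 cm at
    the wrist to ~4.5–6.2 cm at the upper arm, spanning normal-weight to
    obese arm volumes (roughly 1.5–4 L).  With ``grid_cm`` the limb length
    and all knot stations snap to that grid so the profile's knots coincide
    with tape stations and the frustum method is exact on it.
    """
    if grid_cm is not None:
        n_seg = int(rng.integers(8, 12))
        length = n_seg * grid_cm
        pos = [0.0, round(0.35 * n_seg) * grid_cm, round(0.6 * n_seg) * grid_cm, length]
    else:
        length = float(rng.uniform(34.0, 46.0))
        pos = [0.0, 0.35 * length, 0.6 * length, length]
    radii = [
        float(rng.uniform(2.2, 3.2)),
        float(rng.uniform(3.4, 4.6)),
        float(rng.uniform(3.8, 5.2)),
        float(rng.uniform(4.5, 6.2)),
    ]
    knots = [(p, r) for p, r in zip(pos, radii)]
    # drop accidental duplicates from grid snapping
    knots = [k for i, k in enumerate(knots) if i == 0 or k[0] > knots[i - 1][0]]
    return make_limb(
        length_cm=length,
        radius_knots=knots,
        swelling_factor=swelling_factor,
        pose=pose,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
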