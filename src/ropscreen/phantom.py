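"""Synthetic fundus phantoms with analytic ground truth.

The clinical cohort this package targets (RetCam posterior-pole images of
premature infants) is not publicly deposited, so every stage of the
pipeline is exercised on generated phantoms instead: a circular
illuminated field with a saturated outer ring, a bright optic disc, and a
dark vessel tree radiating from the disc.  Vessel centerlines are radial
trunks perturbed by a sinusoid normal to the path; amplitude and spatial
frequency control tortuosity, and a per-unit-arc-length branching
probability controls arborization.  This is the smallest parametric family
that still admits a closed-form arc/chord tortuosity oracle: ground-truth
tortuosity is computed on the continuous curve, before rasterization, so
raster quantization cannot contaminate it.

Two presets emulate the two clinical classes:

* ``healthy`` — low sinusoid amplitude, sparse branching, vessels allowed
  to reach the periphery (vascularization varies with maturity but the
  posterior pole is quiet).
* ``aprop``  — high amplitude and dense branching concentrated within
  6 optic-disc radii of the disc, the hallmark of aggressive posterior
  disease.

The quantitative preset values are calibration choices (the clinical
literature describes the geometry only qualitatively); see the methods
note for the rationale behind each number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SizingError
from .preprocess import FundusImage, ODGeometry

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "HEALTHY_PRESET",
    "APROP_PRESET",
    "generate_phantom",
    "generate_cohort",
    "true_tortuosity",
]

#: Intensity model: background red-channel level, vessel dip depth,
#: optic-disc brightness (8-bit gray levels).
_BG_RGB = (140.0, 70.0, 35.0)
_VESSEL_DIP = 60.0
_OD_RGB = (230.0, 205.0, 120.0)
_OUTSIDE = 5.0


@dataclass
class PhantomParams:
    """Parameters of one synthetic fundus.

    Attributes
    ----------
    image_size : int
        Side of the square raster, pixels.
    od_center : (float, float)
        Optic-disc centre, (row, col).  ``None`` means the image centre.
    od_radius : float
        Optic-disc radius, pixels.
    n_trunks : int
        Number of primary vessels leaving the disc.
    branch_prob : float
        Probability per unit arc length (per pixel) of spawning a child
        branch.
    tortuosity_amp : float
        Amplitude of the sinusoidal centerline perturbation, pixels.
    tortuosity_freq : float
        Perturbation frequency, cycles per 100 px of path length.
    vessel_width : float
        Full width of the rendered vessel, pixels (2-5 is realistic).
    vascular_extent : float
        Maximum vessel reach from the disc centre, in OD radii.
    ring_width : float
        Width of the saturated border ring, pixels.
    noise_sd : float
        Additive Gaussian pixel noise, gray levels.
    seed : int
        Seed for all stochastic choices.
    """

    image_size: int = 640
    od_center: tuple[float, float] | None = None
    od_radius: float = 32.0
    n_trunks: int = 5
    branch_prob: float = 0.02
    tortuosity_amp: float = 2.0
    tortuosity_freq: float = 2.0
    vessel_width: float = 3.0
    vascular_extent: float = 8.0
    ring_width: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.od_center is None:
            return (self.image_size / 2.0, self.image_size / 2.0)
        return self.od_center

    def validate(self) -> None:
        if self.od_radius <= 0:
            raise ValueError("od_radius must be positive")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.tortuosity_amp < 0:
            raise ValueError("tortuosity_amp must be non-negative")
        if self.vascular_extent <= 0:
            raise ValueError("vascular_extent must be positive")
        r0, c0 = self.resolved_center()
        reach = 4.0 * self.od_radius  # OD plus the innermost diagnostic disk
        for v, lim in ((r0, self.image_size), (c0, self.image_size)):
            if v - reach < 0 or v + reach > lim:
                raise SizingError(
                    f"image_size={self.image_size} cannot contain the optic "
                    f"disc plus a 4x-radius diagnostic disk (need the disc "
                    f"centre at least {reach:.0f} px from every border)")


#: Class presets.  Values are pipeline-independent calibration choices,
#: fixed once (see module docstring and docs/methods.md).
HEALTHY_PRESET: dict = {
    "n_trunks": 5,
    "branch_prob": 0.01,
    "tortuosity_amp": 1.0,
    "tortuosity_freq": 1.5,
    "vessel_width": 3.0,
    "vascular_extent": 9.0,
}
APROP_PRESET: dict = {
    "n_trunks": 6,
    "branch_prob": 0.04,
    "tortuosity_amp": 5.0,
    "tortuosity_freq": 2.5,
    "vessel_width": 4.0,
    "vascular_extent": 6.0,
}


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to one phantom."""

    centerlines: list[np.ndarray]  # (N, 2) float polylines, (row, col)
    tortuosity: list[float]        # continuous arc/chord per centerline
    od_geometry: ODGeometry
    label: str = "healthy"
    params: PhantomParams | None = None

    @property
    def n_segments(self) -> int:
        return len(self.centerlines)


def true_tortuosity(polyline: np.ndarray) -> float:
    """Arc length over chord length of a continuous polyline."""
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 2:
        return 1.0
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0.0:
        return np.inf
    return arc / chord


def _sample_curve(start: np.ndarray, direction: np.ndarray, length: float,
                  amp: float, freq: float, phase: float,
                  center: np.ndarray, max_r: float,
                  step: float = 0.5) -> np.ndarray:
    """Sample a sinusoidally perturbed straight path, clipped to the field.

    The path parameter t is arc length along the unperturbed base line;
    the perturbation is ``amp * sin(2*pi*freq*t/100 + phase)`` applied
    along the unit normal.  Sampling stops at the first point leaving the
    disk of radius ``max_r`` about ``center``.
    """
    n = max(int(np.ceil(length / step)) + 1, 2)
    t = np.linspace(0.0, length, n)
    normal = np.array([-direction[1], direction[0]])
    pts = (start[None, :] + t[:, None] * direction[None, :]
           + (amp * np.sin(2.0 * np.pi * freq * t / 100.0 + phase))[:, None]
           * normal[None, :])
    inside = np.linalg.norm(pts - center[None, :], axis=1) <= max_r
    if not inside.all():
        cut = int(np.argmin(inside))
        pts = pts[:max(cut, 2)]
    return pts


def _grow_vessel(start: np.ndarray, direction: np.ndarray, length: float,
                 params: PhantomParams, rng: np.random.Generator,
                 od_center: np.ndarray, field_center: np.ndarray,
                 field_r: float, depth: int,
                 out_lines: list[np.ndarray]) -> None:
    """Grow one vessel curve, splitting it at branch points and recursing.

    Recursion is capped at two generations below the trunk and children
    cover only part of the remaining radial budget, which keeps the tree
    in the dozens of segments a real fundus shows rather than an
    unbounded cascade.
    """
    if length < 8.0 or depth > 2:
        return
    pts = _sample_curve(start, direction, length, params.tortuosity_amp,
                        params.tortuosity_freq, rng.uniform(0, 2 * np.pi),
                        field_center, field_r)
    base_step = length / (len(pts) - 1) if len(pts) > 1 else 0.5

    # Branch events along the base parameter; each splits the parent curve.
    spawn_idx: list[int] = []
    if params.branch_prob > 0 and depth < 2:
        u = rng.random(len(pts))
        hits = np.nonzero(u < params.branch_prob * base_step)[0]
        spawn_idx = [int(i) for i in hits if 4 <= i <= len(pts) - 5]

    cuts = [0] + spawn_idx + [len(pts) - 1]
    cuts = sorted(set(cuts))
    for a, b in zip(cuts[:-1], cuts[1:]):
        piece = pts[a:b + 1]
        if len(piece) >= 2:
            out_lines.append(piece)

    max_reach = params.vascular_extent * params.od_radius
    for i in spawn_idx:
        p = pts[i]
        sign = rng.choice([-1.0, 1.0])
        ang = sign * np.deg2rad(rng.uniform(20.0, 50.0))
        ca, sa = np.cos(ang), np.sin(ang)
        child_dir = np.array([direction[0] * ca - direction[1] * sa,
                              direction[0] * sa + direction[1] * ca])
        radial = float(np.linalg.norm(p - od_center))
        child_len = (max_reach - radial) * rng.uniform(0.3, 0.7)
        _grow_vessel(p, child_dir, child_len, params, rng, od_center,
                     field_center, field_r, depth + 1, out_lines)


def generate_phantom(params: PhantomParams,
                     label: str = "healthy") -> tuple[FundusImage, PhantomTruth]:
    """Render one phantom fundus and its analytic truth.

    Deterministic for a fixed ``params.seed``.  Vessels are rendered as a
    Gaussian-profile intensity dip (dark vessels on a reddish fundus), the
    optic disc as a bright circle, and the field border as a saturated
    ring of the requested width.

    Returns
    -------
    (FundusImage, PhantomTruth)
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    od_center = np.asarray(params.resolved_center(), dtype=float)
    field_center = np.array([size / 2.0, size / 2.0])
    field_r = size / 2.0 - 2.0
    # Centerlines must stay clear of the saturated ring.
    usable_r = field_r - params.ring_width - 3.0

    lines: list[np.ndarray] = []
    max_reach = params.vascular_extent * params.od_radius
    for k in range(params.n_trunks):
        ang = 2.0 * np.pi * k / max(params.n_trunks, 1) + rng.uniform(-0.3, 0.3)
        direction = np.array([np.sin(ang), np.cos(ang)])
        start = od_center + params.od_radius * direction
        _grow_vessel(start, direction, max_reach - params.od_radius, params,
                     rng, od_center, field_center, usable_r, 0, lines)

    torts = [true_tortuosity(pl) for pl in lines]

    # --- raster rendering ------------------------------------------------
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    d_field = np.hypot(rr - field_center[0], cc - field_center[1])
    in_field = d_field <= field_r
    in_ring = in_field & (d_field > field_r - params.ring_width)
    d_od = np.hypot(rr - od_center[0], cc - od_center[1])
    in_od = d_od <= params.od_radius

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = _OUTSIDE
    for ch in range(3):
        img[..., ch][in_field] = _BG_RGB[ch]
        img[..., ch][in_od] = _OD_RGB[ch]

    if lines:
        canvas = np.zeros((size, size), dtype=bool)
        for pl in lines:
            ij = np.round(pl).astype(int)
            ok = ((ij[:, 0] >= 0) & (ij[:, 0] < size)
                  & (ij[:, 1] >= 0) & (ij[:, 1] < size))
            canvas[ij[ok, 0], ij[ok, 1]] = True
        dist = ndimage.distance_transform_edt(~canvas)
        sigma_w = max(params.vessel_width / 2.0, 0.5)
        dip = _VESSEL_DIP * np.exp(-(dist**2) / (2.0 * sigma_w**2))
        dip[~in_field | in_od] = 0.0
        img[..., 0] -= dip
        img[..., 1] -= 0.6 * dip

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=img.shape)
        noise[~in_field] = 0.0
        img += noise
    img[in_ring] = 255.0  # the ring is saturated: it clips any noise
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    od = ODGeometry(endpoint_a=(od_center[0], od_center[1] - params.od_radius),
                    endpoint_b=(od_center[0], od_center[1] + params.od_radius))
    truth = PhantomTruth(centerlines=lines, tortuosity=torts, od_geometry=od,
                         label=label, params=params)
    image = FundusImage(pixels=pixels, id=f"phantom-{label}-{params.seed}")
    return image, truth


def generate_cohort(n_healthy: int, n_aprop: int,
                    preset_overrides: dict | None = None,
                    seed: int = 0,
                    image_size: int = 640) -> list[tuple[FundusImage, PhantomTruth]]:
    """Generate a labelled cohort of phantoms.

    Parameters
    ----------
    n_healthy, n_aprop : int
        Class sizes; the defaults elsewhere in the package mirror a
        screening cohort of 15 healthy and 21 diseased eyes.
    preset_overrides : dict, optional
        ``{"healthy": {...}, "aprop": {...}}`` parameter overrides merged
        on top of the class presets.
    seed : int
        Master seed; per-image seeds are spawned from it reproducibly.

    Returns
    -------
    list of (FundusImage, PhantomTruth), healthy images first.
    """
    if n_healthy < 0 or n_aprop < 0:
        raise ValueError("cohort counts must be non-negative")
    if n_healthy + n_aprop < 2:
        raise ValueError("need at least two images in a cohort")
    overrides = preset_overrides or {}
    rng = np.random.default_rng(seed)
    out: list[tuple[FundusImage, PhantomTruth]] = []
    for label, preset, n in (("healthy", HEALTHY_PRESET, n_healthy),
                             ("aprop", APROP_PRESET, n_aprop)):
        merged = dict(preset)
        merged.update(overrides.get(label, {}))
        for k in range(n):
            p = PhantomParams(image_size=image_size,
                              seed=int(rng.integers(2**31)), **merged)
            img, truth = generate_phantom(p, label=label)
            img = dataclasses.replace(img, id=f"{label}-{k:02d}")
            out.append((img, truth))
    return out
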