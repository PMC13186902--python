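"""Seeded synthetic microscopy data with machine-readable ground truth.

Every generator in this module emulates one class of raw data consumed by the
downstream quantification stages:

* nuclear-stain frames — bright blobs of controlled solidity (intact ellipses
  vs. concave fragments) on a flat background;
* calcium movies — a constant somatic baseline plus localized boxcar (or
  exponentially decaying) transients of known onset, duration, footprint and
  amplitude, under a Poisson-shot + Gaussian-read noise model;
* tracked-point displacement tables — a homogeneous equibiaxial stretch (or a
  rigid translation) with a half-sine temporal profile, as produced by
  indenting a circular elastic membrane;
* puncta images — isotropic Gaussian spots over a (possibly spatially varying)
  diffuse background.

All generators are deterministic given their parameters and seed, and return a
:class:`GroundTruth` record sufficient to repaint every planted object.
Coordinates are (row, col), 0-based, origin top-left, throughout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi

from .exceptions import ValidationError


def _ndi_label8(mask: np.ndarray):
    return _ndi.label(mask, structure=_ndi.generate_binary_structure(2, 2))

SHAPE_CLASSES = ("intact_ellipse", "fragment")
DEFORMATION_MODES = ("equibiaxial", "rigid_translation")

# Fragment geometry: a lune (disk minus an offset larger disk). The constants
# are fixed so that for radius >= 6 px the discrete (pixel-hull) solidity of
# any fragment stays below 0.80 while intact near-circular ellipses stay at or
# above 0.92 — a construction gap comfortably spanning the default 0.9
# intact/fragment cut. (Pixel-hull solidity of even a perfect discrete disk
# dips to ~0.92 at these radii, so larger intact guarantees are not attainable
# for discrete shapes.)
_FRAGMENT_BITE_OFFSET = 0.60  # bite-center distance, in units of the radius
_FRAGMENT_BITE_RADIUS = 1.10  # bite radius, in units of the radius

# Soft radial intensity profile painted inside every nucleus: a flat bright
# core fading to a dim rim. The rim floor keeps the noiseless suprathreshold
# support identical to the geometric footprint.
_PROFILE_RIM = 0.15
_PROFILE_GAIN = 1.4


@dataclass(frozen=True)
class NucleusSpec:
    """One planted nucleus: center (row, col) px, radius px, peak intensity."""

    center: tuple[float, float]
    radius: float
    intensity: float
    shape_class: str = "intact_ellipse"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if self.intensity <= 0:
            raise ValidationError(f"intensity must be > 0, got {self.intensity}")
        if self.shape_class not in SHAPE_CLASSES:
            raise ValidationError(
                f"shape_class must be one of {SHAPE_CLASSES}, got {self.shape_class!r}"
            )


@dataclass(frozen=True)
class TransientSpec:
    """One planted calcium transient inside the soma of cell ``cell_id``."""

    cell_id: int
    onset_frame: int
    duration: int
    footprint_area: int
    amplitude: float

    def __post_init__(self):
        if self.duration < 1:
            raise ValidationError(f"duration must be >= 1 frame, got {self.duration}")
        if self.footprint_area < 1:
            raise ValidationError(
                f"footprint_area must be >= 1 px, got {self.footprint_area}"
            )
        if self.amplitude <= 0:
            raise ValidationError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class DeformationSpec:
    """Membrane deformation: equibiaxial half-sine stretch or rigid translation.

    ``peak_stretch`` is the stretch ratio lambda (1 = undeformed); the profile
    rises from lambda=1 at t=0 to ``peak_stretch`` at t=``rise_time`` and falls
    symmetrically with no dwell, matching an indenter displacement history
    shaped like a half-sine wave (~15 ms rise, ~30 ms total by default).
    """

    mode: str
    peak_stretch: float = 1.0
    rise_time: float = 0.015
    total_duration: float = 0.030
    n_points: int = 12
    temporal_profile: str = "half_sine"

    def __post_init__(self):
        if self.mode not in DEFORMATION_MODES:
            raise ValidationError(
                f"mode must be one of {DEFORMATION_MODES}, got {self.mode!r}"
            )
        if self.temporal_profile != "half_sine":
            raise ValidationError("only the half_sine temporal profile is supported")
        if self.peak_stretch < 1:
            raise ValidationError(f"peak_stretch must be >= 1, got {self.peak_stretch}")
        if self.mode == "rigid_translation" and self.peak_stretch != 1:
            raise ValidationError("rigid_translation requires peak_stretch == 1")
        if self.rise_time <= 0:
            raise ValidationError(f"rise_time must be > 0, got {self.rise_time}")
        if self.total_duration <= 0:
            raise ValidationError("total_duration must be > 0")
        if self.n_points < 3:
            raise ValidationError(f"n_points must be >= 3, got {self.n_points}")


@dataclass
class GroundTruth:
    """Complete record of the planted objects behind one generated dataset."""

    nuclei: list[NucleusSpec] = field(default_factory=list)
    transients: list[TransientSpec] = field(default_factory=list)
    puncta_centers: list[tuple[float, float]] = field(default_factory=list)
    deformation: DeformationSpec | None = None
    seed: int = 0
    # Exact pixel coordinates of each transient footprint, keyed by the index
    # of the transient in ``transients`` — repaintable without the generator.
    transient_footprints: dict[int, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "nuclei": [dataclasses.asdict(n) for n in self.nuclei],
            "transients": [dataclasses.asdict(t) for t in self.transients],
            "puncta_centers": [list(c) for c in self.puncta_centers],
            "deformation": (
                dataclasses.asdict(self.deformation) if self.deformation else None
            ),
            "transient_footprints": {
                str(k): np.asarray(v).tolist()
                for k, v in self.transient_footprints.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        return cls(
            nuclei=[
                NucleusSpec(center=tuple(n.pop("center")), **n) for n in doc["nuclei"]
            ],
            transients=[TransientSpec(**t) for t in doc["transients"]],
            puncta_centers=[tuple(c) for c in doc["puncta_centers"]],
            deformation=(
                DeformationSpec(**doc["deformation"]) if doc["deformation"] else None
            ),
            seed=doc["seed"],
            transient_footprints={
                int(k): np.asarray(v, dtype=np.intp)
                for k, v in doc["transient_footprints"].items()
            },
        )


# ---------------------------------------------------------------------------
# nucleus painting


def _nucleus_geometry(spec: NucleusSpec, index: int, seed: int):
    """Deterministic per-nucleus orientation/axis-ratio drawn from (seed, index)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, index, 0xA5])
    angle = rng.uniform(0.0, math.pi)
    ratio = rng.uniform(0.95, 1.0)
    bite_dir = rng.uniform(0.0, 2 * math.pi)
    return angle, ratio, bite_dir


def _paint_nucleus(spec: NucleusSpec, index: int, seed: int, shape):
    """Return (rows, cols, weights) of the nucleus footprint and its profile."""
    h, w = shape
    r0, c0 = spec.center
    rad = spec.radius
    angle, ratio, bite_dir = _nucleus_geometry(spec, index, seed)

    lo_r = max(0, int(math.floor(r0 - rad - 1)))
    hi_r = min(h, int(math.ceil(r0 + rad + 2)))
    lo_c = max(0, int(math.floor(c0 - rad - 1)))
    hi_c = min(w, int(math.ceil(c0 + rad + 2)))
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dr = rr - r0
    dc = cc - c0

    ca, sa = math.cos(angle), math.sin(angle)
    u = (dr * ca + dc * sa) / rad
    v = (-dr * sa + dc * ca) / (rad * ratio)
    rho2 = u * u + v * v
    mask = rho2 <= 1.0

    if spec.shape_class == "fragment":
        br = r0 + _FRAGMENT_BITE_OFFSET * rad * math.cos(bite_dir)
        bc = c0 + _FRAGMENT_BITE_OFFSET * rad * math.sin(bite_dir)
        bite = (rr - br) ** 2 + (cc - bc) ** 2 <= (_FRAGMENT_BITE_RADIUS * rad) ** 2
        mask &= ~bite
        # the thin lune can pinch off at its tips: keep the largest 8-connected
        # piece so every object is a single component
        comp, k = _ndi_label8(mask)
        if k > 1:
            sizes = np.bincount(comp.ravel())[1:]
            mask = comp == (int(np.argmax(sizes)) + 1)

    profile = _PROFILE_RIM + (1 - _PROFILE_RIM) * np.clip(
        _PROFILE_GAIN * (1.0 - rho2), 0.0, 1.0
    )
    rows, cols = np.nonzero(mask)
    return rows + lo_r, cols + lo_c, profile[mask]


def paint_nuclei_labels(
    specs: list[NucleusSpec], shape: tuple[int, int], seed: int = 0
) -> np.ndarray:
    """Repaint the exact footprint of each nucleus as a label map (order = label)."""
    labels = np.zeros(shape, dtype=np.int32)
    for i, spec in enumerate(specs):
        rows, cols, _ = _paint_nucleus(spec, i, seed, shape)
        labels[rows, cols] = i + 1
    return labels


def _validate_nucleus_layout(specs, shape, min_separation):
    h, w = shape
    for i, s in enumerate(specs):
        r0, c0 = s.center
        if not (s.radius <= r0 <= h - 1 - s.radius and s.radius <= c0 <= w - 1 - s.radius):
            raise ValidationError(
                f"nucleus {i} at {s.center} with radius {s.radius} extends outside "
                f"the {h}x{w} frame"
            )
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            a, b = specs[i], specs[j]
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < a.radius + b.radius + min_separation:
                raise ValidationError(
                    f"nuclei {i} and {j} overlap: center distance {d:.2f} < "
                    f"{a.radius + b.radius + min_separation:.2f} "
                    f"(radii + min_separation)"
                )


def make_nuclei_image(
    specs: list[NucleusSpec],
    shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.1,
    min_separation: float = 2.0,
):
    """Render a single-frame nuclear-stain image plus its ground truth.

    Each nucleus is painted with a soft radial profile (flat bright core, dim
    rim); fragments are concave lunes. Gaussian read noise of ``noise_sd`` is
    added on top. Every nucleus must be at least 5x ``noise_sd`` above
    background at its rim so the noiseless support is recoverable.
    """
    h, w = shape
    if h < 64 or w < 64:
        raise ValidationError(f"shape must be at least 64x64, got {shape}")
    _validate_nucleus_layout(specs, shape, min_separation)
    for i, s in enumerate(specs):
        if noise_sd > 0 and s.intensity < 5 * noise_sd:
            raise ValidationError(
                f"nucleus {i}: intensity {s.intensity:.3g} is below "
                f"5x noise_sd ({5 * noise_sd:.3g})"
            )
    image = np.full(shape, float(background))
    for i, spec in enumerate(specs):
        rows, cols, prof = _paint_nucleus(spec, i, seed, shape)
        image[rows, cols] += spec.intensity * prof
    if noise_sd > 0:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xBEEF])
        image += rng.normal(0.0, noise_sd, size=shape)
    truth = GroundTruth(nuclei=list(specs), seed=seed)
    return image, truth


def random_nuclei_specs(
    n_intact: int,
    n_fragment: int,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    radius_range: tuple[float, float] = (6.0, 10.0),
    intact_intensity: float = 1.0,
    fragment_intensity: float = 0.35,
    min_separation: float = 3.0,
    max_tries: int = 20000,
) -> list[NucleusSpec]:
    """Rejection-sample a non-overlapping monolayer layout (deterministic)."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
    h, w = shape
    specs: list[NucleusSpec] = []
    classes = ["intact_ellipse"] * n_intact + ["fragment"] * n_fragment
    for shape_class in classes:
        intensity = intact_intensity if shape_class == "intact_ellipse" else fragment_intensity
        for _ in range(max_tries):
            rad = rng.uniform(*radius_range)
            r0 = rng.uniform(rad + 1, h - rad - 2)
            c0 = rng.uniform(rad + 1, w - rad - 2)
            ok = all(
                math.hypot(r0 - s.center[0], c0 - s.center[1])
                >= rad + s.radius + min_separation
                for s in specs
            )
            if ok:
                specs.append(
                    NucleusSpec((r0, c0), rad, intensity, shape_class=shape_class)
                )
                break
        else:
            raise ValidationError(
                f"could not place {n_intact + n_fragment} nuclei in {shape} "
                f"after {max_tries} tries"
            )
    return specs


# ---------------------------------------------------------------------------
# calcium movies


def _transient_footprint(cells: np.ndarray, spec: TransientSpec) -> np.ndarray:
    """Pick ``footprint_area`` pixels of the cell, growing out from its centroid.

    Pixels are ranked by distance to the cell centroid with (row, col) as the
    deterministic tie-break, so the footprint is compact and reproducible.
    """
    rows, cols = np.nonzero(cells == spec.cell_id)
    if rows.size == 0:
        raise ValidationError(f"transient references unknown cell_id {spec.cell_id}")
    if spec.footprint_area > rows.size:
        raise ValidationError(
            f"footprint_area {spec.footprint_area} exceeds cell {spec.cell_id} "
            f"area {rows.size}"
        )
    cr, cc = rows.mean(), cols.mean()
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    order = np.lexsort((cols, rows, d2))
    keep = order[: spec.footprint_area]
    return np.column_stack([rows[keep], cols[keep]])


def make_calcium_movie(
    cells: np.ndarray,
    transients: list[TransientSpec],
    T: int = 277,
    baseline: float = 100.0,
    noise: dict | None = None,
    seed: int = 0,
    temporal_profile: str = "boxcar",
):
    """Render a calcium movie: baseline + planted transients + camera noise.

    ``noise`` is ``{"poisson_gain": g, "gaussian_sd": s}``; either component can
    be zero (off). With ``g > 0`` the noiseless movie is treated as a mean
    photon flux: frames become ``Poisson(g * I) / g``. Gaussian read noise of
    sd ``s`` is added afterwards. The default 277 frames mirror a 1 Hz
    confocal recording.
    """
    cells = np.asarray(cells)
    if T < 2:
        raise ValidationError(f"T must be >= 2, got {T}")
    noise = dict(noise or {})
    gain = float(noise.pop("poisson_gain", 0.0))
    gsd = float(noise.pop("gaussian_sd", 0.0))
    if noise:
        raise ValidationError(f"unknown noise keys: {sorted(noise)}")
    if temporal_profile not in ("boxcar", "exp_decay"):
        raise ValidationError(f"unknown temporal_profile {temporal_profile!r}")

    movie = np.full((T,) + cells.shape, float(baseline))
    footprints: dict[int, np.ndarray] = {}
    for i, tr in enumerate(transients):
        if tr.onset_frame < 0 or tr.onset_frame + tr.duration > T:
            raise ValidationError(
                f"transient {i}: frames [{tr.onset_frame}, "
                f"{tr.onset_frame + tr.duration}) fall outside the {T}-frame movie"
            )
        fp = _transient_footprint(cells, tr)
        footprints[i] = fp
        frames = np.arange(tr.onset_frame, tr.onset_frame + tr.duration)
        if temporal_profile == "boxcar":
            weights = np.ones(tr.duration)
        else:
            tau = max(1.0, tr.duration / 3.0)
            weights = np.exp(-np.arange(tr.duration) / tau)
        for f, wgt in zip(frames, weights):
            movie[f, fp[:, 0], fp[:, 1]] += tr.amplitude * wgt

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xCA1C])
    if gain > 0:
        movie = rng.poisson(movie * gain).astype(float) / gain
    if gsd > 0:
        movie += rng.normal(0.0, gsd, size=movie.shape)

    truth = GroundTruth(
        transients=list(transients), seed=seed, transient_footprints=footprints
    )
    return movie, truth


# ---------------------------------------------------------------------------
# displacement fields


def stretch_profile(t: np.ndarray, spec: DeformationSpec) -> np.ndarray:
    """Half-sine stretch history: lambda(t), peaking at ``rise_time``."""
    t = np.asarray(t, dtype=float)
    phase = np.clip(t / (2.0 * spec.rise_time), 0.0, 1.0)
    shape = np.sin(np.pi * phase)
    return 1.0 + (spec.peak_stretch - 1.0) * shape


def make_displacement_field(
    spec: DeformationSpec,
    dt: float,
    seed: int = 0,
    field_radius: float = 200.0,
    center: tuple[float, float] = (256.0, 256.0),
    translation: tuple[float, float] = (8.0, 5.0),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Tracked-point table for a homogeneous deformation of the membrane.

    Points are scattered uniformly in a disc of ``field_radius`` px around
    ``center``. Equibiaxial mode maps each point x0 to
    ``center + lambda(t) * (x0 - center)``; rigid_translation adds a common
    half-sine offset with no shape change. Columns:
    point_id, t_s, x0_px, y0_px, x_px, y_px (x = col, y = row).
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xD15B])
    n = spec.n_points
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = field_radius * np.sqrt(rng.uniform(0.05, 1.0, n))
    y0 = center[0] + rad * np.sin(theta)
    x0 = center[1] + rad * np.cos(theta)

    t = np.arange(0.0, spec.total_duration + dt / 2, dt)
    lam = stretch_profile(t, spec)
    rows = []
    for k, tk in enumerate(t):
        if spec.mode == "equibiaxial":
            xk = center[1] + lam[k] * (x0 - center[1])
            yk = center[0] + lam[k] * (y0 - center[0])
        else:
            shape = math.sin(math.pi * min(tk / (2 * spec.rise_time), 1.0))
            xk = x0 + translation[1] * shape
            yk = y0 + translation[0] * shape
        rows.append(
            pd.DataFrame(
                {
                    "point_id": np.arange(n),
                    "t_s": tk,
                    "x0_px": x0,
                    "y0_px": y0,
                    "x_px": xk,
                    "y_px": yk,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(deformation=spec, seed=seed)
    return table, truth


# ---------------------------------------------------------------------------
# puncta images


def make_puncta_image(
    centers: list[tuple[float, float]],
    spot_sigma: float = 2.0,
    background: float | np.ndarray = 0.1,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    amplitude: float = 1.0,
):
    """Isotropic Gaussian spots of sd ``spot_sigma`` over a diffuse background.

    ``background`` may be a scalar or an H x W array (e.g. a smooth gradient)
    to exercise background-removal steps downstream.
    """
    if spot_sigma <= 0:
        raise ValidationError(f"spot_sigma must be > 0, got {spot_sigma}")
    h, w = shape
    image = np.zeros(shape, dtype=float) + np.asarray(background, dtype=float)
    if image.shape != (h, w):
        raise ValidationError(
            f"background shape {np.shape(background)} does not match {shape}"
        )
    half = int(math.ceil(4 * spot_sigma))
    for i, (r0, c0) in enumerate(centers):
        if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
            raise ValidationError(f"puncta center {i} at {(r0, c0)} is outside {shape}")
        lo_r, hi_r = max(0, int(r0) - half), min(h, int(r0) + half + 1)
        lo_c, hi_c = max(0, int(c0) - half), min(w, int(c0) + half + 1)
        rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        image[lo_r:hi_r, lo_c:hi_c] += amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * spot_sigma**2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5497])
        image += rng.normal(0.0, noise_sd, size=shape)
    truth = GroundTruth(puncta_centers=[tuple(c) for c in centers], seed=seed)
    return image, truth
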