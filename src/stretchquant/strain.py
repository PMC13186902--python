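"""Membrane strain from tracked material points.

The stretch-injury device indents a circular elastic membrane with a
cylindrical post, producing a homogeneous equibiaxial stretch of the culture
surface with a half-sine time course (~15 ms rise, ~30 ms total). Strain is
quantified from material points tracked on the membrane: for each point and
time step the local isotropic stretch ratio lambda is estimated by
least-squares fitting of current pairwise distances against reference
pairwise distances, converted to strain (Green-Lagrange E = (lambda^2 - 1)/2
by default, engineering strain lambda - 1 under the "nominal" convention),
and the per-point strain histories are averaged into a single well strain
history. Peak strain is the maximum of that history and the peak strain rate
is peak strain divided by the rise time — e.g. a peak strain of 0.81 applied
over 15 ms is a strain rate of 54 1/s.

The pairwise-distance fit depends only on point separations, so any
rigid-body motion (translation and/or rotation) yields identically zero
strain by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import IllConditionedError, ValidationError

CONVENTIONS = ("green", "nominal")


@dataclass
class PointTrack:
    """One tracked material point: reference position and per-frame positions."""

    point_id: int
    reference_position: tuple[float, float]  # (x, y)
    positions: np.ndarray  # (N, 2) of (x, y)
    dt: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (N, 2) array")
        if self.positions.shape[0] < 2:
            raise ValidationError("a track needs at least 2 time samples")
        if self.dt <= 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        ref = np.asarray(self.reference_position, dtype=float)
        if not np.allclose(self.positions[0], ref, atol=1e-6):
            raise ValidationError(
                f"track {self.point_id}: first position {self.positions[0]} does not "
                f"match reference {ref}"
            )


@dataclass
class StrainHistory:
    """Mean membrane strain of a well over time, with peak-rate summary."""

    t: np.ndarray
    strain: np.ndarray
    convention: str
    peak_strain: float
    peak_strain_rate: float
    rise_time: float


def green_strain_from_stretch(lam, convention: str = "green"):
    """Strain of a stretch ratio: Green-Lagrange (lambda^2 - 1)/2 or nominal lambda - 1."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValidationError("stretch ratio must be > 0")
    if convention == "green":
        out = (lam**2 - 1.0) / 2.0
    elif convention == "nominal":
        out = lam - 1.0
    else:
        raise ValidationError(f"convention must be one of {CONVENTIONS}")
    return float(out) if out.ndim == 0 else out


def tracks_from_table(table: pd.DataFrame) -> list[PointTrack]:
    """Build tracks from a tidy table (point_id, t_s, x0_px, y0_px, x_px, y_px)."""
    required = {"point_id", "t_s", "x0_px", "y0_px", "x_px", "y_px"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"track table is missing columns {sorted(missing)}")
    tracks = []
    for pid, grp in table.groupby("point_id", sort=True):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy()
        if len(t) < 2:
            raise ValidationError(f"point {pid} has fewer than 2 time samples")
        dt = float(np.median(np.diff(t)))
        tracks.append(
            PointTrack(
                point_id=int(pid),
                reference_position=(float(grp["x0_px"].iloc[0]), float(grp["y0_px"].iloc[0])),
                positions=grp[["x_px", "y_px"]].to_numpy(),
                dt=dt,
            )
        )
    return tracks


def _stretch_per_point(ref: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Per-point isotropic stretch: LS fit of current vs reference distances.

    For point i, lambda_i = sum_j d_ij(t) d_ij(0) / sum_j d_ij(0)^2 over all
    other points j — the least-squares slope through the origin.
    """
    d_ref = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    d_cur = np.linalg.norm(cur[:, None, :] - cur[None, :, :], axis=-1)
    denom = (d_ref**2).sum(axis=1)
    if np.any(denom <= 0):
        raise IllConditionedError("coincident reference points: stretch fit undefined")
    return (d_cur * d_ref).sum(axis=1) / denom


def _rise_time(t: np.ndarray, strain: np.ndarray, atol: float) -> float:
    """Time from first motion to the peak of the mean strain history."""
    i_peak = int(np.argmax(strain))
    quiet = np.nonzero(strain[: i_peak + 1] <= atol)[0]
    i_start = int(quiet[-1]) if quiet.size else 0
    return float(t[i_peak] - t[i_start])


def strain_history_from_tracks(
    tracks: list[PointTrack],
    convention: str = "green",
    motion_atol: float = 1e-9,
) -> StrainHistory:
    """Mean strain history of a well from >= 3 tracked points.

    Per time step the local stretch is fit per point from pairwise distances,
    converted to strain under ``convention``, then averaged across points.
    Collinear or coincident reference layouts are rejected as ill-conditioned.
    """
    if convention not in CONVENTIONS:
        raise ValidationError(f"convention must be one of {CONVENTIONS}")
    if len(tracks) < 3:
        raise ValidationError(f"need >= 3 tracked points, got {len(tracks)}")
    n_t = tracks[0].positions.shape[0]
    dt = tracks[0].dt
    for tr in tracks:
        if tr.positions.shape[0] != n_t or not np.isclose(tr.dt, dt):
            raise ValidationError("all tracks must share one time base")

    ref = np.array([tr.reference_position for tr in tracks], dtype=float)
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(ref).max())) < 2:
        raise IllConditionedError(
            "reference points are collinear or coincident: strain is unidentifiable"
        )

    pos = np.stack([tr.positions for tr in tracks], axis=0)  # (P, N, 2)
    strain = np.empty(n_t)
    for k in range(n_t):
        lam = _stretch_per_point(ref, pos[:, k, :])
        strain[k] = green_strain_from_stretch(lam, convention).mean()

    t = np.arange(n_t) * dt
    peak = float(strain.max())
    rise = _rise_time(t, strain, motion_atol)
    rate = 0.0 if peak <= motion_atol else peak_strain_rate(peak, rise)
    return StrainHistory(
        t=t,
        strain=strain,
        convention=convention,
        peak_strain=peak,
        peak_strain_rate=rate,
        rise_time=rise,
    )


def peak_strain_rate(peak_strain: float, rise_time: float) -> float:
    """Peak strain divided by the time taken to apply it (1/s)."""
    if rise_time <= 0:
        raise ValidationError(f"rise_time must be > 0, got {rise_time}")
    return float(peak_strain) / float(rise_time)


def deformation_gradient_history(tracks: list[PointTrack]) -> np.ndarray:
    """Affine (2x2 deformation gradient) fit per time step, for anisotropy QC.

    Least-squares fit of x(t) = F (x0 - x0_mean) + c; returns an (N, 2, 2)
    array. Principal stretches are the singular values of each F; for a
    homogeneous equibiaxial field both equal lambda(t).
    """
    if len(tracks) < 3:
        raise ValidationError(f"need >= 3 tracked points, got {len(tracks)}")
    ref = np.array([tr.reference_position for tr in tracks], dtype=float)
    pos = np.stack([tr.positions for tr in tracks], axis=0)
    x0 = ref - ref.mean(axis=0)
    n_t = pos.shape[1]
    design = np.hstack([x0, np.ones((len(tracks), 1))])  # (P, 3)
    out = np.empty((n_t, 2, 2))
    for k in range(n_t):
        coeffs, *_ = np.linalg.lstsq(design, pos[:, k, :], rcond=None)
        out[k] = coeffs[:2, :].T
    return out
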