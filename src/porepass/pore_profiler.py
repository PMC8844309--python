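"""Probe-sphere radius and hydrophobicity profiles along pores and portals.

The pathway model follows the HOLE/CHAP family of tools: at each station
along a path direction, the profile radius is the largest clearance of a
spherical probe whose center is confined to the plane through the station,

    f(p) = min_i ( |p - x_i| - r_i ),

maximised over the in-plane position ``p`` subject to a lateral continuity
tether to the previous station's center.  The maximisation is a seeded
multi-start Nelder–Mead search (k = 8 starts around the previous center),
which makes profiles bit-reproducible for a given ``rng_seed``.

Two seeding conventions are provided: the central pore is walked along the
channel axis from a seed point (for a heptameric MscS-like channel, the
center of the pore-gate phenylalanine ring), while side portals are walked
along the in-membrane-plane direction from the portal center toward the
axis, mirroring how cytoplasmic-cage portals of MscS/MSL channels are
profiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structure_io import ChannelAxis, MolecularStructure, residue_center

__all__ = [
    "PathProfile",
    "ProfileEnvelope",
    "KYTE_DOOLITTLE",
    "profile_pore",
    "profile_portal",
    "profile_path",
    "min_radius",
    "hydrophobicity_profile",
    "profile_envelope",
]

#: Kyte–Doolittle residue hydropathy (hydrophobic > 0, hydrophilic < 0).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

STATION_OK = "ok"
STATION_OPEN = "open"  # probe escaped to bulk; walk stopped past here
STATION_UNDEFINED = "undefined"  # no lining residues for hydrophobicity


class ProfileError(Exception):
    pass


@dataclass
class PathProfile:
    """Radius (and optionally hydrophobicity) along a pathway.

    ``stations`` are strictly increasing arc-length coordinates s (Å):
    signed axial distance from the axis origin for pore profiles, signed
    distance from the portal seed toward the axis for portal profiles.
    """

    stations: np.ndarray
    centers: np.ndarray
    radius: np.ndarray
    seed_point: np.ndarray
    direction_mode: str  # "axis-aligned" | "toward-axis"
    hydrophobicity: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)
    barrier_flag: bool | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stations = np.asarray(self.stations, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(np.diff(self.stations) <= 0):
            raise ProfileError("stations must be strictly increasing")
        if np.any(self.radius < 0):
            raise ProfileError("radius must be non-negative")
        if not self.flags:
            self.flags = [STATION_OK] * len(self.stations)


@dataclass
class ProfileEnvelope:
    """Pointwise radius statistics over frames on a common station grid."""

    stations: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_frames: int


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane normal to *direction*."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _clearance_fn(structure: MolecularStructure, escape_radius: float) -> Callable:
    """Return local_clearance(anchor, reach) -> f with
    f(p) = min_i(|p - x_i| - r_i) over atoms within range of the anchor.

    The KD-tree is queried once per station (around the anchor point); the
    returned closure then evaluates clearance against that atom subset,
    which keeps the per-evaluation cost low inside the optimizer.
    """
    pos = structure.positions()
    if len(pos) == 0:
        raise ProfileError("structure has no atoms")
    rad = structure.radii()
    tree = cKDTree(pos)
    r_max = float(rad.max())
    open_value = escape_radius + 1.0

    def local_clearance(anchor: np.ndarray, reach: float) -> Callable:
        idx = tree.query_ball_point(anchor, reach + escape_radius + r_max + 1.0)
        if not idx:
            return lambda p: open_value
        sub_pos = pos[idx]
        sub_rad = rad[idx]

        def clearance(p: np.ndarray) -> float:
            diff = sub_pos - p
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff)) - sub_rad
            return float(d.min())

        return clearance

    return local_clearance


def _maximize_in_plane(
    clearance: Callable,
    origin3: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    prev_uv: np.ndarray,
    tether: float,
    rng: np.random.Generator,
    n_starts: int = 8,
) -> tuple[np.ndarray, float]:
    """Maximise clearance over the plane point origin3 + a*u + b*v with
    |(a,b) - prev_uv| <= tether.  Returns (best_uv, best_clearance)."""

    def neg(xy: np.ndarray) -> float:
        excess = np.linalg.norm(xy - prev_uv) - tether
        penalty = 1e3 * excess if excess > 0 else 0.0
        p = origin3 + xy[0] * u + xy[1] * v
        return -clearance(p) + penalty

    starts = [prev_uv]
    for _ in range(n_starts - 1):
        starts.append(prev_uv + rng.normal(scale=tether / 2.0, size=2))
    best_xy, best_val = prev_uv, neg(prev_uv)
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 100})
        if res.fun < best_val:
            best_val, best_xy = res.fun, res.x
    # clip back inside the tether disk (penalty should already enforce this)
    d = np.linalg.norm(best_xy - prev_uv)
    if d > tether:
        best_xy = prev_uv + (best_xy - prev_uv) * (tether / d)
    p = origin3 + best_xy[0] * u + best_xy[1] * v
    return best_xy, clearance(p)


def profile_path(
    structure: MolecularStructure,
    origin: np.ndarray,
    direction: np.ndarray,
    seed: np.ndarray,
    step: float = 0.25,
    bounds: tuple[float, float] = (-25.0, 25.0),
    rng_seed: int = 0,
    escape_radius: float = 12.0,
    lateral_tether: float | None = None,
    direction_mode: str = "axis-aligned",
) -> PathProfile:
    """Walk the probe outward from the seed station in both directions.

    Stations are ``s = (p - origin)·direction``; the walk stops in a
    direction once the probe escapes laterally beyond ``escape_radius``
    (that station is flagged "open").
    """
    if step <= 0:
        raise ProfileError("step must be positive")
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    origin = np.asarray(origin, float)
    seed = np.asarray(seed, float)
    tether = step if lateral_tether is None else lateral_tether
    local_clearance = _clearance_fn(structure, escape_radius)
    u, v = _plane_basis(direction)

    s_seed = float(np.dot(seed - origin, direction))
    s_lo, s_hi = bounds
    if not (s_lo <= s_seed <= s_hi):
        raise ProfileError(f"seed station {s_seed:.2f} outside bounds {bounds}")
    n_up = int(np.floor((s_hi - s_seed) / step + 1e-9))
    n_dn = int(np.floor((s_seed - s_lo) / step + 1e-9))
    rng = np.random.default_rng(rng_seed)

    def station_opt(s: float, prev_uv: np.ndarray):
        plane_pt = origin + s * direction
        anchor = plane_pt + prev_uv[0] * u + prev_uv[1] * v
        clearance = local_clearance(anchor, tether + step)
        return _maximize_in_plane(clearance, plane_pt, u, v, prev_uv, tether, rng)

    # optimise the seed station first, starting from the seed point itself
    seed_uv = np.array([np.dot(seed - origin, u), np.dot(seed - origin, v)])
    uv0, r0 = station_opt(s_seed, seed_uv)

    def walk(n_steps: int, sign: int, start_uv: np.ndarray):
        out = []
        prev_uv = start_uv
        for k in range(1, n_steps + 1):
            s = s_seed + sign * k * step
            uv, r = station_opt(s, prev_uv)
            open_to_bulk = r > escape_radius
            out.append((s, uv, min(r, escape_radius), open_to_bulk))
            if open_to_bulk:
                break
            prev_uv = uv
        return out

    up = walk(n_up, +1, uv0)
    down = walk(n_dn, -1, uv0)

    records = [(s, uv, r, op) for (s, uv, r, op) in reversed(down)]
    records.append((s_seed, uv0, min(r0, escape_radius), r0 > escape_radius))
    records.extend(up)

    stations = np.array([r[0] for r in records])
    centers = np.array([origin + s * direction + uv[0] * u + uv[1] * v
                        for (s, uv, _, _) in records])
    radius = np.array([max(r[2], 0.0) for r in records])
    flags = [STATION_OPEN if r[3] else STATION_OK for r in records]
    return PathProfile(
        stations=stations,
        centers=centers,
        radius=radius,
        seed_point=seed,
        direction_mode=direction_mode,
        flags=flags,
        metadata={"rng_seed": rng_seed, "step": step, "structure": structure.label},
    )


def profile_pore(
    structure: MolecularStructure,
    axis: ChannelAxis,
    seed: np.ndarray,
    step: float = 0.25,
    bounds: tuple[float, float] = (-25.0, 25.0),
    rng_seed: int = 0,
    escape_radius: float = 12.0,
) -> PathProfile:
    """Radius profile of the central pore along the channel axis.

    ``seed`` is the initial probe position (conventionally the center of the
    pore-gate ring); stations are signed axial distance from ``axis.origin``.
    """
    return profile_path(
        structure, axis.origin, axis.direction, seed,
        step=step, bounds=bounds, rng_seed=rng_seed,
        escape_radius=escape_radius, direction_mode="axis-aligned",
    )


def profile_portal(
    structure: MolecularStructure,
    axis: ChannelAxis,
    portal_residues: Sequence[tuple[str, int]],
    step: float = 0.25,
    bounds: tuple[float, float] = (-10.0, 15.0),
    rng_seed: int = 0,
    escape_radius: float = 12.0,
) -> PathProfile:
    """Radius profile of a cytoplasmic side portal.

    The seed is the geometric center of the portal-lining residues and the
    path direction is the horizontal (in-membrane-plane) unit vector from
    the seed toward the channel axis; s > 0 is inward, s < 0 outward.
    """
    seed = residue_center(structure, portal_residues)
    # component of (axis - seed) perpendicular to the axis direction
    to_axis = axis.origin - seed
    to_axis -= np.dot(to_axis, axis.direction) * axis.direction
    norm = np.linalg.norm(to_axis)
    if norm < 1e-9:
        raise ProfileError("portal seed lies on the channel axis")
    direction = to_axis / norm
    return profile_path(
        structure, seed, direction, seed,
        step=step, bounds=bounds, rng_seed=rng_seed,
        escape_radius=escape_radius, direction_mode="toward-axis",
    )


def min_radius(
    profile: PathProfile, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """(station, radius) of the minimum profile radius within *window*.

    Only stations flagged "ok" participate; ties resolve to the smallest s.
    """
    s = profile.stations
    mask = np.array([f == STATION_OK for f in profile.flags])
    if window is not None:
        lo, hi = window
        mask &= (s >= lo) & (s <= hi)
    if not mask.any():
        raise ProfileError(f"window {window} overlaps no profile stations")
    idx = np.flatnonzero(mask)
    best = idx[np.argmin(profile.radius[idx])]  # argmin returns first minimum
    return float(s[best]), float(profile.radius[best])


def hydrophobicity_profile(
    structure: MolecularStructure,
    profile: PathProfile,
    scale: dict[str, float] | None = None,
    contact_cutoff: float = 6.0,
    r_wet: float = 3.5,
    h_crit: float = 0.0,
) -> PathProfile:
    """Fill per-station hydrophobicity and evaluate a hydration-barrier rule.

    hydrophobicity(s) is the mean scale value over residues with any atom
    within ``contact_cutoff`` of the station center (NaN and flagged
    "undefined" when no residue is in contact).  ``barrier_flag`` is True
    iff any station is simultaneously narrow (radius < r_wet) and apolar
    (hydrophobicity > h_crit) — a simplified hydrophobic-gating heuristic:
    narrow hydrophilic pores and wide hydrophobic pores both stay wetted.
    """
    scale = KYTE_DOOLITTLE if scale is None else scale
    missing = set(KYTE_DOOLITTLE) - set(scale)
    if missing:
        raise ProfileError(f"hydrophobicity scale missing residues: {sorted(missing)}")
    pos = structure.positions()
    tree = cKDTree(pos)
    res_keys = [(a.chain, a.residue_number, a.residue_name) for a in structure.atoms]

    hydro = np.full(len(profile.stations), np.nan)
    flags = list(profile.flags)
    for i, center in enumerate(profile.centers):
        if flags[i] == STATION_OPEN:
            continue
        idx = tree.query_ball_point(center, contact_cutoff)
        residues = {res_keys[j] for j in idx}
        scores = [scale[name] for (_, _, name) in residues if name in scale]
        if scores:
            hydro[i] = float(np.mean(scores))
        else:
            flags[i] = STATION_UNDEFINED
    barrier = bool(
        np.any(
            (profile.radius < r_wet)
            & np.where(np.isnan(hydro), False, hydro > h_crit)
        )
    )
    return PathProfile(
        stations=profile.stations,
        centers=profile.centers,
        radius=profile.radius,
        seed_point=profile.seed_point,
        direction_mode=profile.direction_mode,
        hydrophobicity=hydro,
        flags=flags,
        barrier_flag=barrier,
        metadata=dict(profile.metadata, r_wet=r_wet, h_crit=h_crit),
    )


def profile_envelope(
    frames: Sequence[MolecularStructure],
    axis: ChannelAxis,
    seed: np.ndarray,
    step: float = 0.25,
    bounds: tuple[float, float] = (-25.0, 25.0),
    rng_seed: int = 0,
    escape_radius: float = 12.0,
) -> ProfileEnvelope:
    """Per-station radius statistics over trajectory frames.

    Each frame is profiled independently (a per-frame rng stream derived
    from ``rng_seed`` keeps results reproducible); frames are resampled
    onto the first frame's station grid by linear interpolation.  The s.d.
    uses the n−1 denominator for n ≥ 2 and is 0 for a single frame.
    """
    if len(frames) == 0:
        raise ProfileError("need at least one frame")
    n_atoms = len(frames[0])
    if any(len(f) != n_atoms for f in frames):
        raise ProfileError("frames have incompatible atom counts")
    profiles = [
        profile_pore(f, axis, seed, step=step, bounds=bounds,
                     rng_seed=rng_seed + k, escape_radius=escape_radius)
        for k, f in enumerate(frames)
    ]
    grid = profiles[0].stations
    stack = np.vstack([
        np.interp(grid, p.stations, p.radius) for p in profiles
    ])
    n = len(frames)
    sd = stack.std(axis=0, ddof=1) if n >= 2 else np.zeros_like(grid)
    return ProfileEnvelope(
        stations=grid,
        mean=stack.mean(axis=0),
        sd=sd,
        min=stack.min(axis=0),
        max=stack.max(axis=0),
        n_frames=n,
    )
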