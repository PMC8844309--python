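"""Synthetic inputs with known ground truth for every analysis stage.

Three generators emulate the experimental regimes the analyses assume:

* **Toy channel solids** — pseudo-atom rings stacked along z with analytic
  clearance profiles (ring radius − atom radius), optional C7 side-portal
  holes.  These validate the probe-sphere profiler against closed forms.
* **Brownian ion trajectories** — overdamped Langevin dynamics of ~0.5 M
  worth of monovalent ions in a cylindrical box containing an analytic
  channel solid (membrane slab pierced by a pore, cytoplasmic cage with
  side-portal windows), driven by a uniform field across the channel span.
  The generator emits its own portal→pore passage log, computed with
  labeling code independent of :mod:`porepass.permeation`, so event
  detection can be closed against ground truth exactly.
* **Markov-gating patch sweeps** — N independent two-state channels with a
  pressure-step protocol, open-level current i = γ(V − Erev), exponential
  deactivation after stimulus end and Gaussian recording noise.

All generators are seed-deterministic and return machine-readable ground
truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ephys import SweepTrace, rt_over_f
from .permeation import ChannelGeometry, Compartment, IonTrajectory, PortalAnnulus
from .structure_io import AtomRecord, ChannelAxis, MolecularStructure

__all__ = [
    "ToyChannelSpec",
    "BrownianSpec",
    "GatingSpec",
    "make_toy_channel",
    "simulate_ions",
    "simulate_patch_sweep",
    "make_iv_dataset",
]


class SynthError(Exception):
    pass


# ---------------------------------------------------------------------------
# Toy channel solids


@dataclass
class ToyChannelSpec:
    """Stacked pseudo-atom rings along z (Å) with optional portal holes.

    ``ring_stations``/``ring_radii`` define the wall radius as a function
    of z (linearly interpolated); rings are laid down every
    ``ring_spacing`` Å with ``atoms_per_ring`` uniformly spaced pseudo
    atoms of radius ``atom_radius``.  ``portal_holes`` is a list of
    ``(z, azimuth_deg, aperture_radius)``: wall atoms within the aperture
    of the hole center are omitted.
    """

    ring_stations: Sequence[float]
    ring_radii: Sequence[float]
    atoms_per_ring: int = 48
    atom_radius: float = 1.7
    ring_spacing: float = 0.5
    portal_holes: list[tuple[float, float, float]] = field(default_factory=list)
    residue_names: Sequence[str] | str = "ALA"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.ring_stations = np.asarray(self.ring_stations, dtype=float)
        self.ring_radii = np.asarray(self.ring_radii, dtype=float)
        if np.any(np.diff(self.ring_stations) <= 0):
            raise SynthError("ring stations must be strictly increasing")
        if np.any(self.ring_radii <= self.atom_radius):
            raise SynthError("ring radii must exceed the atom radius")
        if self.atoms_per_ring < 3:
            raise SynthError("need at least 3 atoms per ring")

    def wall_radius(self, z: np.ndarray | float) -> np.ndarray | float:
        return np.interp(z, self.ring_stations, self.ring_radii)

    def _ring_z(self) -> np.ndarray:
        z_lo, z_hi = float(self.ring_stations[0]), float(self.ring_stations[-1])
        n_rings = int(round((z_hi - z_lo) / self.ring_spacing)) + 1
        return np.linspace(z_lo, z_hi, n_rings)

    def analytic_radius(self, z: np.ndarray | float):
        """Analytic on-axis probe clearance at station z.

        By symmetry the optimal probe center sits on the axis, where the
        distance to every atom of ring k is sqrt(R_k² + (z_k − z)²)
        independent of azimuth, so

            radius(z) = min_k sqrt(R_k² + (z_k − z)²) − atom_radius,

        which reduces to wall radius − atom radius inside a cylinder and
        includes the wall-slope correction on cones/hourglasses.
        """
        zk = self._ring_z()
        rk = np.asarray(self.wall_radius(zk), dtype=float)
        zz = np.atleast_1d(np.asarray(z, dtype=float))
        d = np.sqrt(rk[None, :] ** 2 + (zk[None, :] - zz[:, None]) ** 2)
        out = d.min(axis=1) - self.atom_radius
        return out if np.ndim(z) else float(out[0])


def make_toy_channel(spec: ToyChannelSpec) -> tuple[MolecularStructure, ToyChannelSpec]:
    """Build the pseudo-atom solid; returns (structure, spec-with-analytics).

    Rings are jitter-free; each ring is one pseudo-residue (residue numbers
    increase with z) so hydrophobicity profiling sees one residue name per
    ring.  The returned spec doubles as the analytic profile via
    :meth:`ToyChannelSpec.analytic_radius`.
    """
    z_lo, z_hi = float(spec.ring_stations[0]), float(spec.ring_stations[-1])
    n_rings = int(round((z_hi - z_lo) / spec.ring_spacing)) + 1
    z_values = np.linspace(z_lo, z_hi, n_rings)
    if isinstance(spec.residue_names, str):
        resnames = [spec.residue_names] * n_rings
    else:
        resnames = [spec.residue_names[k % len(spec.residue_names)] for k in range(n_rings)]

    holes = [
        (
            np.array([
                spec.wall_radius(zh) * math.cos(math.radians(az)),
                spec.wall_radius(zh) * math.sin(math.radians(az)),
                zh,
            ]),
            ap,
        )
        for (zh, az, ap) in spec.portal_holes
    ]

    atoms: list[AtomRecord] = []
    serial = 0
    for k, z in enumerate(z_values):
        ring_r = float(spec.wall_radius(z))
        for m in range(spec.atoms_per_ring):
            theta = 2 * math.pi * m / spec.atoms_per_ring
            pos = np.array([ring_r * math.cos(theta), ring_r * math.sin(theta), z])
            if any(np.linalg.norm(pos - hc) <= ap for hc, ap in holes):
                continue
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=f"C{m + 1}",  # unique within the ring residue
                    element="C",
                    residue_name=resnames[k],
                    residue_number=k + 1,
                    chain="A",
                    position=pos,
                    vdw_radius=spec.atom_radius,
                )
            )
    return MolecularStructure(atoms=atoms, label="toy-channel"), spec


# ---------------------------------------------------------------------------
# Brownian ion trajectories


@dataclass
class BrownianSpec:
    """Overdamped Langevin ions in an analytic channel solid.

    Defaults mirror a driven-permeation MD regime: a −425 mV driving
    potential across the channel span, monovalent anions at ~0.5 M in the
    box, bulk chloride diffusivity (≈2.0e−9 m²/s → 203 Å²/ns) and 100 ns
    of dynamics.  ``dt`` must satisfy sqrt(2·D·dt) ≤ aperture/4.
    """

    diffusion: float = 203.0  # Å²/ns
    potential: float = -425.0  # mV across the channel span
    n_ions: int = 85
    ion_charge: float = -1.0
    dt: float = 0.002  # ns
    total_time: float = 100.0  # ns
    rng_seed: int = 0
    sample_every: int = 10  # record every k-th step
    mobility: float | None = None  # Å/ns per (e·mV/Å); None → Einstein D/kT
    temperature: float = 298.15
    drift_everywhere: bool = False  # apply the field outside the channel span too
    # geometry (Å)
    pore_radius: float = 4.0
    cage_radius: float = 12.0
    wall_thickness: float = 3.0
    z_pore_top: float = 15.0
    z_pore_bottom: float = -10.0
    z_cage_bottom: float = -40.0
    portal_z: tuple[float, float] = (-30.0, -20.0)
    box_radius: float = 30.0
    z_box: tuple[float, float] = (-60.0, 40.0)
    # "side": portal windows in the cage side wall (MscS-like topology);
    # "axial": a central aperture in the cage floor — a simplified topology
    # for which ballistic strong-drift flux has a closed form.
    portal_mode: str = "side"
    floor_hole_radius: float = 6.0  # axial mode only
    reinject_radius: float | None = None  # axial mode: reinjection disk radius

    def geometry(self) -> ChannelGeometry:
        """Compartment geometry matching the analytic solid.

        In side mode the portal annulus spans the wall band (with a 2 Å
        margin) over the portal z window, so any wall transit shows up as a
        PORTAL frame; in axial mode it is a disk over the floor aperture.
        """
        if self.portal_mode == "side":
            portal = PortalAnnulus(
                r_range=(self.cage_radius, self.cage_radius + self.wall_thickness + 2.0),
                z_range=self.portal_z,
            )
        else:
            portal = PortalAnnulus(
                r_range=(0.0, self.floor_hole_radius),
                z_range=self.portal_z,
            )
        return ChannelGeometry(
            cylinder_radius=self.cage_radius,
            z_extracellular=self.z_pore_top,
            z_pore_top=self.z_pore_top,
            z_pore_bottom=self.z_pore_bottom,
            z_cage_bottom=self.z_cage_bottom,
            portals=[portal],
        )

    def validate(self) -> None:
        if self.portal_mode not in ("side", "axial"):
            raise SynthError(f"unknown portal_mode {self.portal_mode!r}")
        step_rms = math.sqrt(2 * self.diffusion * self.dt)
        narrow = [self.pore_radius, self.portal_z[1] - self.portal_z[0]]
        if self.portal_mode == "axial":
            narrow.append(self.floor_hole_radius)
        aperture = min(narrow)
        if step_rms > aperture / 4:
            raise SynthError(
                f"unstable dt: rms step {step_rms:.2f} Å exceeds a quarter of the "
                f"narrowest aperture ({aperture:.2f} Å)"
            )
        if self.portal_mode == "side":
            ordered = (self.z_box[0] < self.z_cage_bottom < self.portal_z[0]
                       < self.portal_z[1] < self.z_pore_bottom < self.z_pore_top
                       < self.z_box[1])
        else:
            ordered = (self.z_box[0] < self.portal_z[0] < self.portal_z[1]
                       <= self.z_cage_bottom < self.z_pore_bottom < self.z_pore_top
                       < self.z_box[1])
        if not ordered:
            raise SynthError("geometry z ordering violated")


def _forbidden(spec: BrownianSpec, pts: np.ndarray) -> np.ndarray:
    """Boolean mask: point lies inside the wall solid (membrane slab with a
    pore hole, cage side wall, and a cage floor whose openness depends on
    the portal mode)."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r = np.hypot(x, y)
    wall_hi = spec.cage_radius + spec.wall_thickness
    # membrane/protein slab pierced by the pore
    slab = (z >= spec.z_pore_bottom) & (z <= spec.z_pore_top) & (r > spec.pore_radius)
    if spec.portal_mode == "side":
        # cage side wall, open at the portal z window
        side = (
            (z >= spec.z_cage_bottom) & (z < spec.z_pore_bottom)
            & (r >= spec.cage_radius) & (r <= wall_hi)
            & ~((z >= spec.portal_z[0]) & (z <= spec.portal_z[1]))
        )
        floor = (
            (z >= spec.z_cage_bottom - spec.wall_thickness) & (z < spec.z_cage_bottom)
            & (r <= wall_hi)
        )
    else:
        # closed side wall down to the floor slab; floor pierced centrally
        side = (
            (z >= spec.portal_z[0]) & (z < spec.z_pore_bottom)
            & (r >= spec.cage_radius) & (r <= wall_hi)
        )
        floor = (
            (z >= spec.portal_z[0]) & (z <= spec.portal_z[1])
            & (r > spec.floor_hole_radius) & (r <= wall_hi)
        )
    return slab | side | floor


def _label_points(spec: BrownianSpec, pts: np.ndarray) -> np.ndarray:
    """Generator-side compartment labeling (independent of permeation.py)."""
    geom = spec.geometry()
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r = np.hypot(x, y)
    lab = np.full(len(pts), int(Compartment.BULK_CYT), dtype=np.int8)
    lab[z > geom.z_extracellular] = int(Compartment.BULK_EXT)
    p = geom.portals[0]
    lab[(r >= p.r_range[0]) & (r <= p.r_range[1])
        & (z >= p.z_range[0]) & (z <= p.z_range[1])] = int(Compartment.PORTAL)
    inside = r <= geom.cylinder_radius
    lab[inside & (z >= geom.z_cage_bottom) & (z < geom.z_pore_bottom)] = int(Compartment.CAGE)
    lab[inside & (z >= geom.z_pore_bottom) & (z <= geom.z_pore_top)] = int(Compartment.PORE)
    return lab


def _truth_passages(spec: BrownianSpec, times: np.ndarray, frames: np.ndarray) -> list[dict]:
    """Walk the generator's own state machine over the emitted frames."""
    C = Compartment
    log: list[dict] = []
    n_ions = frames.shape[1]
    labels = np.stack([_label_points(spec, frames[i]) for i in range(len(frames))])
    for j in range(n_ions):
        entry = None
        seen_pore = False
        for i in range(len(times)):
            lab = labels[i, j]
            if lab == C.BULK_CYT:
                entry, seen_pore = None, False
            elif lab == C.PORTAL and entry is None:
                entry = float(times[i])
            elif lab == C.PORE and entry is not None:
                seen_pore = True
            elif lab == C.BULK_EXT and entry is not None and seen_pore:
                log.append({"ion": j, "t_entry": entry, "t_exit": float(times[i]),
                            "portal": 0})
                entry, seen_pore = None, False
    return log


def simulate_ions(spec: BrownianSpec) -> tuple[IonTrajectory, list[dict]]:
    """Run the Brownian dynamics; returns (trajectory, passage log).

    Per step: Δx = v·dt·ẑ + N(0, 2·D·dt) with drift v = μ·q·V/L inside the
    channel span (μ from the Einstein relation unless overridden); moves
    ending inside the wall solid or outside the box are rejected
    (approximate reflecting boundaries); ions leaving the top of the box
    are reinjected uniformly into the bottom reservoir, keeping the ion
    count constant.  The passage log lists completed portal→pore→bulk
    transits on the emitted frames.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n_steps = int(round(spec.total_time / spec.dt))
    kT = rt_over_f(spec.temperature)  # mV per e
    mob = spec.diffusion / kT if spec.mobility is None else spec.mobility
    span = spec.z_pore_top - spec.z_cage_bottom
    drift_v = mob * spec.ion_charge * spec.potential / span  # Å/ns, +z upward
    sigma = math.sqrt(2 * spec.diffusion * spec.dt)

    def reinject(n: int) -> np.ndarray:
        """Uniform positions in the bottom reservoir (BULK_CYT)."""
        if spec.portal_mode == "side":
            r_lo = spec.cage_radius + spec.wall_thickness + 1.0
            rr = np.sqrt(rng.uniform(r_lo**2, spec.box_radius**2, n))
        else:
            r_hi = spec.reinject_radius or spec.box_radius
            rr = np.sqrt(rng.uniform(0.0, r_hi**2, n))
        th = rng.uniform(0, 2 * math.pi, n)
        zz = rng.uniform(spec.z_box[0], spec.z_box[0] + 6.0, n)
        return np.column_stack([rr * np.cos(th), rr * np.sin(th), zz])

    # initial state: all ions in the cytoplasmic reservoir
    pos = reinject(spec.n_ions)
    frames = [pos.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        if spec.drift_everywhere:
            in_channel = np.ones(len(pos), dtype=bool)
        else:
            in_channel = (pos[:, 2] >= spec.z_cage_bottom) & (pos[:, 2] <= spec.z_pore_top)
        drift = np.zeros_like(pos)
        drift[in_channel, 2] = drift_v * spec.dt
        prop = pos + drift + rng.normal(scale=sigma, size=pos.shape)

        # reinjection at the top reservoir boundary
        out_top = prop[:, 2] > spec.z_box[1]
        if out_top.any():
            prop[out_top] = reinject(int(out_top.sum()))

        # reject moves into the solid or out of the box
        r = np.hypot(prop[:, 0], prop[:, 1])
        bad = _forbidden(spec, prop) | (r > spec.box_radius) | (prop[:, 2] < spec.z_box[0])
        prop[bad] = pos[bad]
        pos = prop
        if step % spec.sample_every == 0:
            frames.append(pos.copy())
            times.append(step * spec.dt)

    frames = np.asarray(frames)
    times = np.asarray(times)
    axis = ChannelAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))
    traj = IonTrajectory(
        times=times, ion_positions=frames, axis=axis, ion_charge=spec.ion_charge
    )
    return traj, _truth_passages(spec, times, frames)


# ---------------------------------------------------------------------------
# Patch-clamp sweeps


@dataclass
class GatingSpec:
    """Two-state Markov gating under a pressure-step protocol.

    Defaults emulate a single wild-type-like channel: γ = 270 pS in
    symmetric 150 mM NaCl (Erev = 0) held at −80 mV, a 1 s, −70 mmHg
    pressure pulse sampled at 20 kHz, deactivation τ = 0.477 s, and 1 pA
    Gaussian recording noise.
    """

    n_channels: int = 1
    gamma: float = 270.0  # pS
    erev: float = 0.0  # mV
    voltage: float = -80.0  # mV
    open_rate: float = 50.0  # 1/s while the stimulus is on
    close_rate_during: float = 5.0  # 1/s while the stimulus is on
    tau_deact: float = 0.477  # s; closing rate 1/tau after stimulus end
    noise_sigma: float = 1.0  # pA
    sampling_rate: float = 20000.0  # Hz
    stim_start: float = 0.5  # s
    stim_duration: float = 1.0  # s
    pressure: float = -70.0  # mmHg
    total_time: float = 3.0  # s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.open_rate, self.tau_deact, self.noise_sigma + 1,
               self.sampling_rate, self.n_channels) <= 0:
            raise SynthError("rates, tau, sampling and channel count must be positive")


def simulate_patch_sweep(spec: GatingSpec) -> tuple[SweepTrace, dict]:
    """Simulate one sweep; returns (trace, ground truth).

    Channels open at ``open_rate`` and close at ``close_rate_during``
    while the pressure step is on; after stimulus end they cannot reopen
    and close at 1/τ_deact, giving an ensemble-mean exponential decay.
    I(t) = N_open(t)·γ·(V − Erev)/1000 + N(0, σ) in pA.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = int(round(spec.total_time * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    dt = 1.0 / spec.sampling_rate
    stim_on = (t >= spec.stim_start) & (t < spec.stim_start + spec.stim_duration)
    pressure = np.where(stim_on, spec.pressure, 0.0)

    p_open = 1.0 - math.exp(-spec.open_rate * dt)
    p_close_on = 1.0 - math.exp(-spec.close_rate_during * dt)
    p_close_off = 1.0 - math.exp(-dt / spec.tau_deact)

    state = np.zeros(spec.n_channels, dtype=bool)
    n_open = np.empty(n, dtype=np.int32)
    u = rng.random((n, spec.n_channels))
    for i in range(n):
        if stim_on[i]:
            opening = (~state) & (u[i] < p_open)
            closing = state & (u[i] < p_close_on)
        else:
            opening = np.zeros_like(state)
            closing = state & (u[i] < p_close_off)
        state = (state | opening) & ~closing
        n_open[i] = int(state.sum())

    open_level = spec.gamma * (spec.voltage - spec.erev) / 1000.0  # pA
    current = n_open * open_level + rng.normal(scale=spec.noise_sigma, size=n)
    trace = SweepTrace(
        time=t, current=current, pressure=pressure, voltage=spec.voltage,
        sampling_rate=spec.sampling_rate,
    )
    truth = {
        "gamma_pS": spec.gamma,
        "erev_mV": spec.erev,
        "open_level_pA": open_level,
        "tau_deact_s": spec.tau_deact,
        "stim_end_s": spec.stim_start + spec.stim_duration,
        "n_open": n_open,
    }
    return trace, truth


def make_iv_dataset(
    gamma: float,
    erev: float,
    voltages: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Synthetic single-channel I–V points: i = γ(V − Erev)/1000 + N(0, σ)."""
    if len(voltages) < 3:
        raise SynthError("need at least 3 voltages")
    rng = np.random.default_rng(seed)
    out = []
    for v in voltages:
        i = gamma * (v - erev) / 1000.0
        if sigma > 0:
            i += rng.normal(scale=sigma)
        out.append((float(v), float(i)))
    return out
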