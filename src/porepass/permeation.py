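"""Ion permeation analysis for channel trajectories.

Given tracked ion coordinates and a distance-constraint channel geometry
around the pore axis, this module assigns each ion at each frame to one of
five compartments (cytoplasmic bulk, side portal, cytoplasmic cage, pore,
extracellular bulk), detects completed permeation events — a passage that
enters through a side portal, traverses the pore, and reaches the
extracellular bulk without falling back to the cytoplasmic bulk — and
turns event counts into a conductance estimate via G = Q/(t·V).

Also provided: axial z-tracks with periodic unwrapping, ion–residue
first-contact ladders along an event, χ1 rotamer classification of a
pore-gate side chain, and a water-count wetting occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .structure_io import ChannelAxis, MolecularStructure

__all__ = [
    "Compartment",
    "IonTrajectory",
    "ChannelGeometry",
    "PortalAnnulus",
    "CompartmentSeries",
    "CrossingEvent",
    "ConductanceEstimate",
    "RotamerSeries",
    "assign_compartments",
    "detect_crossings",
    "estimate_conductance",
    "z_tracks",
    "contact_ladder",
    "chi1_series",
    "dihedral",
    "wetting_occupancy",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C


class PermeationError(Exception):
    pass


class Compartment(IntEnum):
    BULK_CYT = 0
    PORTAL = 1
    CAGE = 2
    PORE = 3
    BULK_EXT = 4


@dataclass
class IonTrajectory:
    """Uniform-timestep tracked-ion coordinates.

    times are in ns; ion_positions has shape (n_frames, n_ions, 3) in Å.
    ``box`` (optional) holds orthorhombic box edge lengths for periodic
    unwrapping.  ``protein_frames`` optionally carries a per-frame
    :class:`MolecularStructure` for contact analyses.
    """

    times: np.ndarray
    ion_positions: np.ndarray
    axis: ChannelAxis
    ion_charge: np.ndarray | float = -1.0
    ion_ids: list | None = None
    protein_frames: Sequence[MolecularStructure] | None = None
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ion_positions = np.asarray(self.ion_positions, dtype=float)
        if self.ion_positions.ndim != 3 or self.ion_positions.shape[2] != 3:
            raise PermeationError("ion_positions must have shape (frames, ions, 3)")
        if len(self.times) != self.ion_positions.shape[0]:
            raise PermeationError("times and ion_positions frame counts differ")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
            raise PermeationError("times must be strictly increasing and uniform")
        if self.ion_ids is None:
            self.ion_ids = list(range(self.ion_positions.shape[1]))
        self.ion_charge = np.broadcast_to(
            np.asarray(self.ion_charge, dtype=float), (self.ion_positions.shape[1],)
        ).copy()
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.ion_positions.shape[0]

    @property
    def n_ions(self) -> int:
        return self.ion_positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0


@dataclass(frozen=True)
class PortalAnnulus:
    """One portal window: radial range from the axis and axial z range (Å)."""

    r_range: tuple[float, float]
    z_range: tuple[float, float]


@dataclass
class ChannelGeometry:
    """Distance-based compartment boundaries along the channel axis (Å).

    z boundaries must be strictly ordered
    z_cage_bottom < z_pore_bottom < z_pore_top <= z_extracellular.
    """

    cylinder_radius: float = 8.0
    z_extracellular: float = 25.0
    z_pore_top: float = 25.0
    z_pore_bottom: float = 0.0
    z_cage_bottom: float = -30.0
    portals: list[PortalAnnulus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.z_cage_bottom < self.z_pore_bottom < self.z_pore_top <= self.z_extracellular):
            raise PermeationError("geometry z boundaries must be strictly ordered")
        if self.cylinder_radius <= 0:
            raise PermeationError("cylinder_radius must be positive")


@dataclass
class CompartmentSeries:
    """Per-(frame, ion) compartment labels plus the portal index (or -1)."""

    times: np.ndarray
    labels: np.ndarray  # (frames, ions) of Compartment values
    portal_index: np.ndarray  # (frames, ions); -1 when not in a portal
    ion_ids: list
    ion_charge: np.ndarray


@dataclass(frozen=True)
class CrossingEvent:
    """One completed permeation: portal entry → pore → extracellular bulk."""

    ion: object
    t_entry: float  # ns, first PORTAL frame of the completed passage
    t_exit: float  # ns, first BULK_EXT frame
    portal: int
    charge: float = -1.0

    def __post_init__(self) -> None:
        if self.t_exit <= self.t_entry:
            raise PermeationError("event must have t_exit > t_entry")

    @property
    def transit(self) -> float:
        return self.t_exit - self.t_entry


@dataclass(frozen=True)
class ConductanceEstimate:
    n_events: int
    charge_per_event: float  # e
    duration: float  # ns
    potential: float  # mV
    conductance: float  # pS


@dataclass
class RotamerSeries:
    """χ1 dihedral series (degrees, (−180, 180]) with rotamer labels."""

    chi1: np.ndarray
    labels: list[str]


# ---------------------------------------------------------------------------


def assign_compartments(traj: IonTrajectory, geom: ChannelGeometry) -> CompartmentSeries:
    """Label every (frame, ion) with its compartment.

    Precedence on boundary ties: PORE > CAGE > PORTAL > bulk.  Radial
    distance and axial z are measured against ``traj.axis``.
    """
    pos = traj.ion_positions
    if np.any(~np.isfinite(pos)):
        bad = np.argwhere(~np.isfinite(pos))[0]
        raise PermeationError(f"NaN/inf ion coordinate at frame {bad[0]}, ion {bad[1]}")
    flat = pos.reshape(-1, 3)
    z = traj.axis.axial(flat).reshape(pos.shape[:2])
    r = traj.axis.radial(flat).reshape(pos.shape[:2])

    labels = np.full(pos.shape[:2], int(Compartment.BULK_CYT), dtype=np.int8)
    portal_idx = np.full(pos.shape[:2], -1, dtype=np.int16)

    labels[z > geom.z_extracellular] = int(Compartment.BULK_EXT)
    for k, p in enumerate(geom.portals):
        in_portal = (
            (r >= p.r_range[0]) & (r <= p.r_range[1])
            & (z >= p.z_range[0]) & (z <= p.z_range[1])
        )
        labels[in_portal] = int(Compartment.PORTAL)
        portal_idx[in_portal] = k
    in_cyl = r <= geom.cylinder_radius
    cage = in_cyl & (z >= geom.z_cage_bottom) & (z < geom.z_pore_bottom)
    pore = in_cyl & (z >= geom.z_pore_bottom) & (z <= geom.z_pore_top)
    labels[cage] = int(Compartment.CAGE)
    labels[pore] = int(Compartment.PORE)
    portal_idx[cage | pore] = -1
    return CompartmentSeries(
        times=traj.times,
        labels=labels,
        portal_index=portal_idx,
        ion_ids=list(traj.ion_ids),
        ion_charge=traj.ion_charge,
    )


def detect_crossings(series: CompartmentSeries, charge: float | None = None) -> list[CrossingEvent]:
    """Extract completed permeation events from a compartment series.

    An event is a maximal run in which an ion first visits PORTAL, later
    visits PORE, and then reaches BULK_EXT, with no intervening BULK_CYT
    (which resets the state machine).  Partial passages yield no event.
    """
    events: list[CrossingEvent] = []
    C = Compartment
    for j, ion in enumerate(series.ion_ids):
        q = float(series.ion_charge[j]) if charge is None else float(charge)
        entry_t: float | None = None
        entry_portal = -1
        seen_pore = False
        for i, lab in enumerate(series.labels[:, j]):
            t = float(series.times[i])
            if lab == C.BULK_CYT:
                entry_t, seen_pore, entry_portal = None, False, -1
            elif lab == C.PORTAL:
                if entry_t is None:
                    entry_t = t
                    entry_portal = int(series.portal_index[i, j])
            elif lab == C.PORE:
                if entry_t is not None:
                    seen_pore = True
            elif lab == C.BULK_EXT:
                if entry_t is not None and seen_pore:
                    events.append(
                        CrossingEvent(ion=ion, t_entry=entry_t, t_exit=t,
                                      portal=entry_portal, charge=q)
                    )
                    entry_t, seen_pore, entry_portal = None, False, -1
    return events


def estimate_conductance(
    n_events: int, charge: float, duration: float, potential: float
) -> ConductanceEstimate:
    """Conductance from event counting: G = Q/(t·V), reported in pS.

    ``charge`` is the per-event charge in elementary units, ``duration`` in
    ns, ``potential`` in mV.  The sign of the potential and charge is
    discarded; the magnitude is reported.
    """
    if duration <= 0:
        raise PermeationError("duration must be positive")
    if potential == 0:
        raise PermeationError("potential must be non-zero")
    q_coulomb = n_events * abs(charge) * ELEMENTARY_CHARGE
    g_siemens = q_coulomb / ((duration * 1e-9) * (abs(potential) * 1e-3))
    return ConductanceEstimate(
        n_events=int(n_events),
        charge_per_event=float(charge),
        duration=float(duration),
        potential=float(potential),
        conductance=g_siemens * 1e12,
    )


def z_tracks(traj: IonTrajectory, ions: Sequence | None = None) -> dict:
    """Per-ion (t, z) series along the axis, periodic-unwrapped if a box is
    present (minimal-image per-step displacements accumulated from frame 0)."""
    ids = list(traj.ion_ids)
    want = ids if ions is None else list(ions)
    cols = []
    for ion in want:
        if ion not in ids:
            raise PermeationError(f"unknown ion id {ion!r}")
        cols.append(ids.index(ion))
    pos = traj.ion_positions[:, cols, :]
    if traj.box is not None and len(pos) > 1:
        steps = np.diff(pos, axis=0)
        steps -= traj.box * np.round(steps / traj.box)
        pos = np.concatenate([pos[:1], pos[:1] + np.cumsum(steps, axis=0)], axis=0)
    z = traj.axis.axial(pos.reshape(-1, 3)).reshape(pos.shape[:2])
    return {ion: (traj.times.copy(), z[:, k]) for k, ion in enumerate(want)}


_BASIC_NITROGENS = {"NZ", "NH1", "NH2", "NE", "NE2", "ND1", "N1"}


def contact_ladder(
    traj: IonTrajectory,
    event: CrossingEvent,
    residues: Sequence[tuple[str, int]],
    cutoff: float = 4.0,
    handover: tuple | None = None,
    contact_atoms: set[str] = _BASIC_NITROGENS,
) -> tuple[list[tuple[tuple, float]], bool]:
    """First-contact times of an ion with charged portal residues during an
    event, ordered by time, plus a handover unidirectionality flag.

    A contact is any selected side-chain nitrogen/charged-group atom within
    ``cutoff`` Å of the ion.  ``handover=(donor, acceptor)`` (defaults to
    the last two selectors) defines the flag: True iff after the ion's
    first acceptor contact it never re-contacts the donor within the event.
    """
    if traj.protein_frames is None:
        raise PermeationError("contact_ladder requires protein_frames")
    ids = list(traj.ion_ids)
    j = ids.index(event.ion)
    mask = (traj.times >= event.t_entry) & (traj.times <= event.t_exit)
    frames = np.flatnonzero(mask)
    if handover is None:
        if len(residues) < 2:
            raise PermeationError("need >= 2 residues (or explicit handover pair)")
        handover = (tuple(residues[-2]), tuple(residues[-1]))
    donor, acceptor = tuple(handover[0]), tuple(handover[1])

    first_contact: dict[tuple, float] = {}
    donor_contacts: list[float] = []
    acceptor_contacts: list[float] = []
    for i in frames:
        ion_pos = traj.ion_positions[i, j]
        struct = traj.protein_frames[i]
        for sel in residues:
            key = tuple(sel)
            chain, resnum = sel
            atoms = struct.select(
                chain=None if chain in ("*", None) else chain,
                residue_number=int(resnum),
            )
            pts = [a.position for a in atoms if a.name in contact_atoms]
            if not pts:
                continue
            d = np.linalg.norm(np.array(pts) - ion_pos, axis=1).min()
            if d <= cutoff:
                t = float(traj.times[i])
                first_contact.setdefault(key, t)
                if key == donor:
                    donor_contacts.append(t)
                if key == acceptor:
                    acceptor_contacts.append(t)
    ladder = sorted(first_contact.items(), key=lambda kv: kv[1])
    if acceptor_contacts:
        t_acc = min(acceptor_contacts)
        unidirectional = not any(t > t_acc for t in donor_contacts)
    else:
        unidirectional = False
    return ladder, unidirectional


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees, in (−180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def _classify_chi1(chi1: float) -> str:
    if 120.0 <= chi1 <= 180.0 or -180.0 < chi1 < -120.0:
        return "trans"
    if -120.0 <= chi1 < 0.0:
        return "gauche-"
    return "gauche+"


def chi1_series(
    frames: Sequence[MolecularStructure], residue: tuple[str, int]
) -> RotamerSeries:
    """χ1 (N–CA–CB–CG) rotamer series of one residue across frames.

    Labels: trans for χ1 ∈ [120, 180] ∪ (−180, −120), gauche− for
    [−120, 0), gauche+ for [0, 120).
    """
    chain, resnum = residue
    chi_vals = []
    labels = []
    for k, struct in enumerate(frames):
        atoms = {
            a.name: a.position
            for a in struct.select(
                chain=None if chain in ("*", None) else chain,
                residue_number=int(resnum),
            )
        }
        for need in ("N", "CA", "CB", "CG"):
            if need not in atoms:
                raise PermeationError(
                    f"frame {k}: residue {residue} missing atom {need} for chi1"
                )
        chi = dihedral(atoms["N"], atoms["CA"], atoms["CB"], atoms["CG"])
        chi_vals.append(chi)
        labels.append(_classify_chi1(chi))
    return RotamerSeries(chi1=np.array(chi_vals), labels=labels)


def wetting_occupancy(
    waters: IonTrajectory,
    region: tuple[tuple[float, float], tuple[float, float]],
    min_waters: int = 1,
) -> float:
    """Fraction of frames in which ≥ min_waters water oxygens occupy the
    region ((z_lo, z_hi), (r_lo, r_hi)) around the axis."""
    (z_lo, z_hi), (r_lo, r_hi) = region
    if not (z_lo < z_hi) or not (r_lo < r_hi) or r_hi <= 0:
        raise PermeationError("empty wetting region")
    pos = waters.ion_positions
    flat = pos.reshape(-1, 3)
    z = waters.axis.axial(flat).reshape(pos.shape[:2])
    r = waters.axis.radial(flat).reshape(pos.shape[:2])
    inside = (z >= z_lo) & (z <= z_hi) & (r >= r_lo) & (r <= r_hi)
    counts = inside.sum(axis=1)
    return float(np.mean(counts >= min_waters))
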