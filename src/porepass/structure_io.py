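"""Reading, writing and basic geometry of channel structures.

A :class:`MolecularStructure` is a flat, ordered list of
:class:`AtomRecord` with chain grouping — deliberately simpler than a full
crystallographic hierarchy, since everything downstream (pore profiling,
compartment geometry) only needs coordinates, van der Waals radii and
residue identity.  PDB and mmCIF parsing is delegated to ``gemmi``;
alternate locations are resolved to the highest-occupancy conformer at load
time so downstream code never sees duplicated atoms.

The channel's membrane-normal symmetry axis is estimated from a ring
selection (e.g. the pore-gate phenylalanine ring of a heptameric
mechanosensitive channel) as the direction of least dispersion of the ring
points; its sign is fixed by a caller-supplied extracellular reference
selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "ChannelAxis",
    "BONDI_RADII",
    "load_structure",
    "write_pdb",
    "assign_vdw_radii",
    "symmetry_axis",
    "residue_center",
    "parse_selection",
]

#: Bondi-style van der Waals radii (Å) by element symbol.  Values follow the
#: widely used Bondi/UFF-adjacent set for the elements common in protein
#: models; anything absent falls back to a caller-supplied default.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.94,
    "MN": 1.97,
    "SE": 1.90,
}


class StructureError(Exception):
    """Raised for unreadable files, bad selections or degenerate geometry."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates (Å) and an optional vdW radius (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    vdw_radius: float | None = None
    icode: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise StructureError(f"atom {self.serial}: vdw_radius must be positive")


@dataclass
class MolecularStructure:
    """An ordered collection of atoms grouped by chain."""

    atoms: list[AtomRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serial numbers")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> dict[str, list[AtomRecord]]:
        out: dict[str, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.chain, []).append(a)
        return out

    def positions(self) -> np.ndarray:
        """(N, 3) coordinate array in Å."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms])

    def radii(self) -> np.ndarray:
        """(N,) vdW radii; raises if any atom lacks one."""
        vals = [a.vdw_radius for a in self.atoms]
        if any(v is None for v in vals):
            raise StructureError("vdW radii not assigned; call assign_vdw_radii first")
        return np.array(vals, dtype=float)

    def select(self, **criteria) -> list[AtomRecord]:
        """Filter atoms by equality on chain / residue_number / residue_name /
        name / element.  ``chain='*'`` (or omitting the key) matches all."""
        out = []
        for a in self.atoms:
            ok = True
            for key, want in criteria.items():
                if want in (None, "*"):
                    continue
                have = getattr(a, key)
                if isinstance(want, (list, tuple, set, frozenset)):
                    ok = have in want
                else:
                    ok = have == want
                if not ok:
                    break
            if ok:
                out.append(a)
        return out

    def with_positions(self, positions: np.ndarray) -> "MolecularStructure":
        """Copy of the structure with coordinates replaced (same order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise StructureError("position array shape mismatch")
        return MolecularStructure(
            atoms=[replace(a, position=p) for a, p in zip(self.atoms, positions)],
            label=self.label,
        )


@dataclass(frozen=True)
class ChannelAxis:
    """Oriented pore axis: +direction points to the extracellular side."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise StructureError("axis direction must be non-zero")
            d = d / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def axial(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate along the axis (Å) for an (N,3) or (3,) array."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        s = pts @ self.direction
        return s if np.asarray(points).ndim == 2 else float(s[0])

    def radial(self, points: np.ndarray) -> np.ndarray:
        """Distance from the axis line (Å)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        axial = np.outer(pts @ self.direction, self.direction)
        r = np.linalg.norm(pts - axial, axis=1)
        return r if np.asarray(points).ndim == 2 else float(r[0])


# ---------------------------------------------------------------------------
# I/O


def _altloc_filter(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep the highest-occupancy conformer of
    each atom name (ties: first encountered)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        key = atom.name
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occ > best[key].occ:
            best[key] = atom
    return [best[k] for k in order]


def load_structure(path: str | Path, format: str | None = None) -> MolecularStructure:
    """Read a PDB or mmCIF file into a :class:`MolecularStructure`.

    Parameters
    ----------
    path : file path
    format : ``"pdb"``, ``"mmcif"`` or None (sniff from the extension).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise StructureError(f"unknown structure format {format!r} (expected pdb or mmcif)")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    serial = 0
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in _altloc_filter(residue):
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=atom.element.name.upper(),
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        icode=(residue.seqid.icode or "").strip(),
                        occupancy=atom.occ,
                    )
                )
    return MolecularStructure(atoms=atoms, label=path.stem)


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """Write the structure as a PDB file (fixed-width, 3 decimal places)."""
    st = gemmi.Structure()
    st.name = structure.label or "porepass"
    model = gemmi.Model("1")
    for chain_name, chain_atoms in structure.chains.items():
        chain = gemmi.Chain(chain_name)
        # group consecutive atoms into residues before insertion: gemmi's
        # add_residue stores a copy, so residues must be complete first
        groups: list[tuple[tuple, list[AtomRecord]]] = []
        for a in chain_atoms:
            key = (a.residue_number, a.residue_name, a.icode)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(a)
        for (resnum, resname, icode), members in groups:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            for a in members:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element.capitalize())
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Radii


def assign_vdw_radii(
    structure: MolecularStructure,
    table: Mapping[str, float] | None = None,
    default: float = 1.5,
) -> MolecularStructure:
    """Return a copy of *structure* with vdW radii assigned by element.

    ``table`` overrides/extends the shipped Bondi-style table; elements
    absent from both get ``default`` with a logged warning.  Atom-name
    heuristics (first letter) cover records with an empty element column.
    """
    if default <= 0:
        raise StructureError("default vdW radius must be positive")
    merged = dict(BONDI_RADII)
    if table:
        merged.update({k.upper(): float(v) for k, v in table.items()})
    if not merged:
        raise StructureError("radius table is empty")

    missing: set[str] = set()
    new_atoms = []
    for a in structure.atoms:
        elem = a.element.upper()
        if not elem or elem == "X":
            # fall back to the first alphabetic character of the atom name
            letters = [c for c in a.name if c.isalpha()]
            elem = letters[0].upper() if letters else ""
        r = merged.get(elem)
        if r is None:
            missing.add(a.element or a.name)
            r = default
        new_atoms.append(replace(a, vdw_radius=r))
    if missing:
        msg = f"no vdW radius for element(s) {sorted(missing)}; using default {default} Å"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return MolecularStructure(atoms=new_atoms, label=structure.label)


# ---------------------------------------------------------------------------
# Selections and geometry


def parse_selection(text: str) -> dict:
    """Parse ``"chain=A,resid=572,name=CA"`` into select() criteria.

    ``resid`` may be a comma-free list joined by ``+`` (``resid=572+575``).
    """
    crit: dict = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise StructureError(f"bad selection token {part!r}")
        key, val = part.split("=", 1)
        key = key.strip().lower()
        val = val.strip()
        if key in {"resid", "residue", "residue_number"}:
            nums = [int(v) for v in val.split("+")]
            crit["residue_number"] = nums[0] if len(nums) == 1 else nums
        elif key == "chain":
            crit["chain"] = val
        elif key in {"resname", "residue_name"}:
            crit["residue_name"] = val
        elif key == "name":
            crit["name"] = val
        elif key == "element":
            crit["element"] = val.upper()
        else:
            raise StructureError(f"unknown selection key {key!r}")
    return crit


def _selected_positions(structure: MolecularStructure, selection) -> np.ndarray:
    if isinstance(selection, str):
        selection = parse_selection(selection)
    if isinstance(selection, Mapping):
        atoms = structure.select(**selection)
    else:
        atoms = list(selection)
    if not atoms:
        raise StructureError(f"selection {selection!r} matched no atoms")
    return np.array([a.position for a in atoms])


def symmetry_axis(
    structure: MolecularStructure,
    selection,
    extracellular_ref=None,
) -> ChannelAxis:
    """Estimate the channel's symmetry (pore) axis from a ring selection.

    The axis origin is the centroid of the selected atoms and the direction
    is the eigenvector of *smallest* dispersion of their covariance — the
    normal of the ring plane.  ``extracellular_ref`` (a selection whose
    centroid lies on the extracellular side) fixes the sign so that
    +direction points extracellular; without it the sign is arbitrary.
    """
    pts = _selected_positions(structure, selection)
    if len(pts) < 3:
        raise StructureError("axis selection must contain at least 3 atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    # degenerate if the two largest spreads do not dominate the smallest,
    # i.e. points are collinear (two ~zero evals) or coincident (all ~zero)
    scale = float(np.max(evals))
    if scale <= 0 or evals[1] / scale < 1e-10:
        raise StructureError("degenerate axis selection (collinear or coincident points)")
    direction = evecs[:, 0]  # smallest eigenvalue
    if extracellular_ref is not None:
        ref = _selected_positions(structure, extracellular_ref).mean(axis=0)
        if np.dot(ref - centroid, direction) < 0:
            direction = -direction
    return ChannelAxis(origin=centroid, direction=direction)


def residue_center(
    structure: MolecularStructure,
    selectors: Sequence[tuple[str, int]] | Iterable,
) -> np.ndarray:
    """Unweighted mean position (Å) of all atoms of the selected residues.

    ``selectors`` is a list of ``(chain, residue_number)`` pairs; chain
    ``"*"`` matches any chain.
    """
    positions = []
    for sel in selectors:
        chain, resnum = sel
        atoms = structure.select(
            chain=None if chain in ("*", None) else chain, residue_number=int(resnum)
        )
        if not atoms:
            raise StructureError(f"selector {sel!r} resolved no atoms")
        positions.extend(a.position for a in atoms)
    return np.array(positions).mean(axis=0)
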