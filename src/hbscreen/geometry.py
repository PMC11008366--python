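"""Annotated monomer geometries, XYZ I/O and pose realisation.

Monomer geometries are planar templates living in the z = 0 plane with their
hydrogen-bond sites ordered along +x and their bond directions along +y (the
*canonical frame*).  Each site carries an annotation naming its anchor atom
(the donor hydrogen, or the acceptor heavy atom), the donor heavy atom where
applicable, and the in-plane hydrogen-bond direction.

XYZ files are plain text; pose exports are multi-frame XYZ with the register
metadata (flip, shift, contacts, gap) on the comment line.  A sidecar CSV
holds the site annotations (columns: site, role, anchor, heavy, dx, dy, dz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .endgroups import Role
from .errors import AnnotationError, GeometryError
from .poses import Alignment, PairPose

__all__ = [
    "SiteAnnotation",
    "MonomerGeometry",
    "DimerGeometry",
    "build_pose_geometry",
    "read_xyz",
    "write_xyz",
    "read_annotations",
    "write_annotations",
    "planarity_rms",
    "COLLISION_THRESHOLD",
    "PLANARITY_TOLERANCE",
]

#: Intermonomer distances below this value (in angstrom) flag a steric collision.
COLLISION_THRESHOLD = 1.0
#: Maximum RMS out-of-plane deviation (angstrom) for a monomer to count as planar.
PLANARITY_TOLERANCE = 0.1


@dataclass(frozen=True)
class SiteAnnotation:
    """Mapping from one pattern site to atoms of the monomer geometry.

    ``anchor`` is the atom defining the hydrogen-bond interface: the donor H
    for a donor site, the acceptor heavy atom for an acceptor site.
    ``heavy`` is the donor heavy atom (N) for donors, ``None`` otherwise.
    ``direction`` is the in-plane unit vector along which the hydrogen bond
    forms (lone-pair direction for acceptors).
    """

    site: int
    role: Role
    anchor: int
    heavy: Optional[int]
    direction: Tuple[float, float, float] = (0.0, 1.0, 0.0)


@dataclass
class MonomerGeometry:
    """Cartesian coordinates plus per-site annotations for one end group."""

    symbols: List[str]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    sites: List[SiteAnnotation] = field(default_factory=list)
    comment: str = ""
    amino_nitrogens: List[int] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.coords):
            raise GeometryError(
                f"{len(self.symbols)} symbols but {len(self.coords)} coordinates"
            )
        for s in self.sites:
            for idx in (s.anchor, s.heavy):
                if idx is not None and not 0 <= idx < len(self.coords):
                    raise AnnotationError(
                        f"site {s.site}: atom index {idx} out of range"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def site(self, index: int) -> SiteAnnotation:
        for s in self.sites:
            if s.site == index:
                return s
        raise AnnotationError(f"no annotation for site {index}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "MonomerGeometry":
        """Rigidly transformed copy; annotations follow the atoms."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        coords = self.coords @ rotation.T + translation
        sites = [
            replace(s, direction=tuple(rotation @ np.asarray(s.direction, float)))
            for s in self.sites
        ]
        return MonomerGeometry(list(self.symbols), coords, sites, self.comment,
                               list(self.amino_nitrogens))


@dataclass
class DimerGeometry:
    """Two monomers combined; the first ``n_x`` atoms belong to the first."""

    symbols: List[str]
    coords: np.ndarray
    n_x: int
    comment: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


def planarity_rms(coords: np.ndarray) -> float:
    """RMS deviation from the best-fit plane through the atoms."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    centred = coords - coords.mean(axis=0)
    # smallest singular vector = plane normal
    _, svals, _ = np.linalg.svd(centred, full_matrices=False)
    return float(svals[-1] / math.sqrt(len(coords)))


def _check_canonical_frame(geom: MonomerGeometry, planarity_tol: float) -> None:
    z = geom.coords[:, 2]
    if float(np.sqrt(np.mean(z ** 2))) > planarity_tol + 1e-9:
        raise GeometryError(
            "monomer is not planar within tolerance "
            f"(RMS z = {np.sqrt(np.mean(z ** 2)):.3f} A > {planarity_tol} A); "
            "pose construction expects canonical-frame monomers"
        )
    if not geom.sites:
        raise AnnotationError("monomer has no site annotations")
    for s in geom.sites:
        d = np.asarray(s.direction, float)
        d = d / np.linalg.norm(d)
        if abs(d[1]) < 0.99:
            raise GeometryError(
                f"site {s.site}: hydrogen-bond direction {tuple(s.direction)} is "
                "not along +/-y; canonicalise the monomer first"
            )


_ROT_Z180 = np.diag([-1.0, -1.0, 1.0])   # in-plane rotation: face the partner
_ROT_X180 = np.diag([1.0, -1.0, -1.0])   # flip about the site row axis


def build_pose_geometry(x_geom: MonomerGeometry, y_geom: MonomerGeometry,
                        a: Alignment, gap: float = 2.0,
                        collision_threshold: float = COLLISION_THRESHOLD,
                        planarity_tol: float = PLANARITY_TOLERANCE) -> PairPose:
    """Realise one register as a rigid 3D dimer starting geometry.

    The second monomer is rotated 180 degrees in-plane (``flip=False``) or
    about the site-row axis (``flip=True``) so the two site rows face each
    other antiparallel, then translated so that for every contact the
    interface atoms sit ``gap`` angstrom apart along the hydrogen-bond
    direction.  For donor-acceptor contacts the interface atoms are the donor
    H and the acceptor atom, i.e. the H···acceptor distance equals ``gap``
    exactly.

    A pose whose monomers come closer than ``collision_threshold`` anywhere
    is returned flagged (``collided=True``), never dropped silently.
    """
    _check_canonical_frame(x_geom, planarity_tol)
    _check_canonical_frame(y_geom, planarity_tol)
    rot = _ROT_X180 if a.flip else _ROT_Z180
    y_t = y_geom.transformed(rot, np.zeros(3))

    # translation fixed by the first donor-acceptor contact if there is one
    # (same-role facing registers carry no H...acceptor distance constraint)
    hbond = [(i, j) for i, j in a.contacts
             if x_geom.site(i).role is not y_t.site(j).role]
    i0, j0 = hbond[0] if hbond else a.contacts[0]
    sx = x_geom.site(i0)
    sy = y_t.site(j0)
    dx = np.asarray(sx.direction, float)
    target = x_geom.coords[sx.anchor] + gap * dx / np.linalg.norm(dx)
    translation = target - y_t.coords[sy.anchor]
    y_t = y_t.transformed(np.eye(3), translation)

    # verify every intended hydrogen-bond contact
    for i, j in hbond:
        si, sj = x_geom.site(i), y_t.site(j)
        d = float(np.linalg.norm(y_t.coords[sj.anchor] - x_geom.coords[si.anchor]))
        if abs(d - gap) > 1e-6:
            raise GeometryError(
                f"contact ({i},{j}): H...acceptor distance {d:.6f} A != gap {gap} A; "
                "site rows are not commensurate"
            )

    diff = x_geom.coords[:, None, :] - y_t.coords[None, :, :]
    min_dist = float(np.sqrt((diff ** 2).sum(-1)).min())
    collided = min_dist < collision_threshold

    comment = (
        f"flip={int(a.flip)} shift={a.shift} "
        f"contacts={';'.join(f'{i},{j}' for i, j in a.contacts)} gap={gap}"
    )
    dimer = DimerGeometry(
        symbols=list(x_geom.symbols) + list(y_t.symbols),
        coords=np.vstack([x_geom.coords, y_t.coords]),
        n_x=x_geom.n_atoms,
        comment=comment,
    )
    return PairPose(alignment=a, geometry=dimer, gap=gap, collided=collided)


# ---------------------------------------------------------------------------
# XYZ I/O (plain text; per-frame comment lines carry pose metadata)

def write_xyz(path, frames, mode: str = "w") -> None:
    """Write one or more ``(symbols, coords, comment)`` frames to ``path``.

    ``frames`` may also be a single :class:`MonomerGeometry` /
    :class:`DimerGeometry` or a sequence of them.
    """
    frames = _as_frames(frames)
    with open(path, mode) as fh:
        for symbols, coords, comment in frames:
            coords = np.asarray(coords, float).reshape(-1, 3)
            fh.write(f"{len(symbols)}\n{comment}\n")
            for sym, (x, y, z) in zip(symbols, coords):
                fh.write(f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _as_frames(obj):
    if isinstance(obj, (MonomerGeometry, DimerGeometry)):
        obj = [obj]
    frames = []
    for item in obj:
        if isinstance(item, (MonomerGeometry, DimerGeometry)):
            frames.append((item.symbols, item.coords, item.comment))
        else:
            symbols, coords = item[0], item[1]
            comment = item[2] if len(item) > 2 else ""
            frames.append((symbols, coords, comment))
    return frames


def read_xyz(path) -> List[Tuple[List[str], np.ndarray, str]]:
    """Read a (possibly multi-frame) XYZ file."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            natoms = int(lines[k].strip())
        except ValueError:
            raise GeometryError(f"{path}: expected atom count on line {k + 1}")
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        block = lines[k + 2: k + 2 + natoms]
        if len(block) != natoms:
            raise GeometryError(f"{path}: truncated frame at line {k + 1}")
        symbols, coords = [], []
        for ln in block:
            parts = ln.split()
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append((symbols, np.asarray(coords), comment))
        k += 2 + natoms
    return frames


def write_annotations(path, sites: Sequence[SiteAnnotation]) -> None:
    rows = [
        {
            "site": s.site,
            "role": s.role.value,
            "anchor": s.anchor,
            "heavy": -1 if s.heavy is None else s.heavy,
            "dx": s.direction[0],
            "dy": s.direction[1],
            "dz": s.direction[2],
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path) -> List[SiteAnnotation]:
    df = pd.read_csv(path)
    required = {"site", "role", "anchor", "heavy", "dx", "dy", "dz"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        heavy = int(row["heavy"])
        out.append(SiteAnnotation(
            site=int(row["site"]),
            role=Role(row["role"]),
            anchor=int(row["anchor"]),
            heavy=None if heavy < 0 else heavy,
            direction=(float(row["dx"]), float(row["dy"]), float(row["dz"])),
        ))
    return out
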