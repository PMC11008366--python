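"""Per-pose binding energies: surrogate scorer and external-table ingestion.

Binding energies are reported positive for bound complexes throughout
(``BE = E_X + E_Y - E_complex``), matching the convention of quantum
chemistry screens of hydrogen-bonded dimers where favourable pairs land in
the 7-23 kcal/mol range.

Two sources are supported:

* a built-in **surrogate scorer** — a transparent additive model in the
  spirit of secondary-electrostatic-interaction schemes for multiply
  hydrogen-bonded complexes: each facing donor-acceptor contact contributes a
  primary attraction, adjacent contacts exchange diagonal secondary
  cross-terms (attractive for unlike roles, repulsive for like roles),
  acceptor-acceptor registers pay a lone-pair repulsion, and donor-donor
  registers bind only to the extent the amino groups are pyramidal (a planar,
  conjugated amino group cannot act as an acceptor);
* **ingestion of CSV energy tables** exported from external quantum-chemistry
  runs (DFTB+/PSI4 style), including counterpoise-corrected complex energies
  and rigid in-complex fragment energies, from which ``BE_relax`` and
  ``BE_rigid`` derive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .endgroups import EndGroup, Role
from .errors import EnergyTableError, NoPlanarPoseError, \
    UndefinedQuantityError
from .poses import Alignment, PairPose, contact_kinds, mirror

__all__ = [
    "HARTREE_TO_KCAL",
    "EnergyRecord",
    "SurrogateParams",
    "binding_energy",
    "be_relax",
    "be_rigid",
    "raw_binding_energy",
    "surrogate_pair_energy",
    "select_best_pose",
    "read_energy_table",
    "write_energy_table",
]

HARTREE_TO_KCAL = 627.509474

_REQUIRED_COLUMNS = [
    "group_x", "group_y", "pose_id", "E_complex", "E_X_isolated", "E_Y_isolated",
]
_OPTIONAL_COLUMNS = ["E_complex_CP", "E_X_in_complex", "E_Y_in_complex"]


@dataclass
class EnergyRecord:
    """Component energies of one pose of one pair (kcal/mol)."""

    group_x: str
    group_y: str
    pose_id: str
    E_complex: float
    E_X_isolated: float
    E_Y_isolated: float
    E_complex_CP: Optional[float] = None
    E_X_in_complex: Optional[float] = None
    E_Y_in_complex: Optional[float] = None
    extra: Dict[str, object] = field(default_factory=dict)

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.group_x, self.group_y, self.pose_id)


def binding_energy(E_X: float, E_Y: float, E_complex: float) -> float:
    """Energy released on complex formation; positive = bound."""
    return E_X + E_Y - E_complex


def raw_binding_energy(record: EnergyRecord) -> float:
    """Binding energy from the uncorrected complex energy."""
    return binding_energy(record.E_X_isolated, record.E_Y_isolated,
                          record.E_complex)


def be_relax(record: EnergyRecord) -> float:
    """Binding energy vs independently relaxed monomers, from the
    counterpoise-corrected complex energy."""
    if record.E_complex_CP is None:
        raise UndefinedQuantityError(
            f"BE_relax undefined for {record.key}: E_complex_CP missing"
        )
    return binding_energy(record.E_X_isolated, record.E_Y_isolated,
                          record.E_complex_CP)


def be_rigid(record: EnergyRecord) -> float:
    """Interaction energy of the two frozen in-complex fragments."""
    if record.E_complex_CP is None:
        raise UndefinedQuantityError(
            f"BE_rigid undefined for {record.key}: E_complex_CP missing"
        )
    if record.E_X_in_complex is None or record.E_Y_in_complex is None:
        raise UndefinedQuantityError(
            f"BE_rigid undefined for {record.key}: in-complex fragment "
            "energies missing"
        )
    return binding_energy(record.E_X_in_complex, record.E_Y_in_complex,
                          record.E_complex_CP)


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate hydrogen-bond scorer (kcal/mol).

    ``P_N``/``P_O`` are the primary donor→pyridinic-N / donor→keto-O bond
    strengths; ``S`` the magnitude of a diagonal secondary cross-term;
    ``beta`` scales how well a pyramidal amino group serves as an acceptor in
    a donor-donor register; ``R_AA`` the acceptor-acceptor lone-pair
    repulsion; ``sigma_noise`` an optional seeded Gaussian jitter emulating
    pose-optimisation scatter.
    """

    P_N: float = 6.0
    P_O: float = 5.0
    S: float = 1.5
    beta: float = 0.6
    R_AA: float = 1.0
    sigma_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("P_N", "P_O", "S", "R_AA", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


def _primary_term(kx, ky, px: float, py: float, p: SurrogateParams) -> float:
    if kx.role is not ky.role:  # donor facing acceptor
        acceptor = ky if kx.role is Role.DONOR else kx
        return p.P_N if acceptor.flavor.name == "PYRIDINIC_N" else p.P_O
    if kx.role is Role.DONOR:  # D-D: pyramidal amine may accept
        return p.beta * (1.0 - min(px, py)) * p.P_N
    return -p.R_AA  # A-A lone-pair repulsion


def _noise(x_code: str, y_code: str, a: Alignment, m: int, n: int,
           params: SurrogateParams) -> float:
    if params.sigma_noise == 0.0:
        return 0.0
    # key symmetric under argument swap: describe the pose from both ends
    k1 = f"{x_code}|{y_code}|{a.flip:d}|{a.shift}"
    am = mirror(a, m, n)
    k2 = f"{y_code}|{x_code}|{am.flip:d}|{am.shift}"
    digest = zlib.crc32(min(k1, k2).encode())
    rng = np.random.default_rng([params.seed % (2 ** 31), digest])
    return float(rng.normal(0.0, params.sigma_noise))


def surrogate_pair_energy(x: EndGroup, y: EndGroup, a: Alignment,
                          params: SurrogateParams = SurrogateParams()) -> float:
    """Surrogate binding energy (kcal/mol, positive = bound) of one register.

    Sum over contacts of the primary term, plus two diagonal secondary
    cross-terms of magnitude ``S`` for every adjacent pair of contacting
    registers (positive when the crossing sites have unlike roles, negative
    for like roles), plus optional seeded Gaussian noise.  Deterministic for
    ``sigma_noise=0``; symmetric under swapping the two groups.
    """
    kinds = contact_kinds(x.pattern, y.pattern, a)  # validates the alignment
    total = 0.0
    for kx, ky in kinds:
        total += _primary_term(kx, ky, x.planarity, y.planarity, params)
    ordered = sorted(zip(a.contacts, kinds), key=lambda c: c[0][0])
    for (c1, k1), (c2, k2) in zip(ordered, ordered[1:]):
        if c2[0] - c1[0] != 1:
            continue  # only adjacent registers exchange secondary terms
        for ka, kb in ((k1[0], k2[1]), (k2[0], k1[1])):
            total += params.S if ka.role is not kb.role else -params.S
    total += _noise(x.code, y.code, a, len(x.pattern), len(y.pattern), params)
    return total


def select_best_pose(poses: Sequence[Tuple[PairPose, float]],
                     planarity_ok: Callable[[PairPose], bool] = None
                     ) -> Tuple[PairPose, float]:
    """Best pose = maximum binding energy among poses passing the planarity
    predicate; ties broken by fewer contacts, then lowest ``(flip, shift)``.

    Raises :class:`NoPlanarPoseError` (carrying the rejected poses) when
    nothing passes.
    """
    if not poses:
        raise NoPlanarPoseError("empty pose list")
    if planarity_ok is None:
        planarity_ok = lambda pose: True  # noqa: E731
    passing = [(p, e) for p, e in poses if planarity_ok(p)]
    if not passing:
        raise NoPlanarPoseError(
            f"all {len(poses)} poses rejected by the planarity predicate",
            rejected=[p for p, _ in poses],
        )
    return min(
        passing,
        key=lambda pe: (-pe[1], pe[0].alignment.n_contacts,
                        pe[0].alignment.flip, pe[0].alignment.shift),
    )


# ---------------------------------------------------------------------------
# CSV energy tables

_UNIT_FACTORS = {"kcal/mol": 1.0, "hartree": HARTREE_TO_KCAL, "ha": HARTREE_TO_KCAL}
_ENERGY_COLUMNS = ["E_complex", "E_X_isolated", "E_Y_isolated"] + _OPTIONAL_COLUMNS


def read_energy_table(path, unit: str = None) -> List[EnergyRecord]:
    """Read an external energy table (CSV with header) into records.

    Units come from a per-row ``unit`` column or the ``unit`` argument
    (default kcal/mol); hartree values are converted with
    1 hartree = 627.509474 kcal/mol.  Unknown columns are preserved in
    ``record.extra``.  Duplicate keys with conflicting energies raise a
    row-addressed :class:`EnergyTableError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyTableError(f"{path}: missing required columns {missing}")
    known = set(_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS + ["unit"])
    extra_cols = [c for c in df.columns if c not in known]

    records: List[EnergyRecord] = []
    seen: Dict[Tuple[str, str, str], Tuple[int, tuple]] = {}
    for pos, (row_label, row) in enumerate(df.iterrows()):
        rowno = pos + 2  # header is line 1
        row_unit = unit or "kcal/mol"
        if "unit" in df.columns and not pd.isna(row["unit"]):
            row_unit = str(row["unit"]).strip().lower()
        if row_unit not in _UNIT_FACTORS:
            raise EnergyTableError(
                f"{path} row {rowno}: unknown unit {row_unit!r} "
                f"(expected one of {sorted(set(_UNIT_FACTORS))})"
            )
        factor = _UNIT_FACTORS[row_unit]
        values = {}
        for col in _ENERGY_COLUMNS:
            if col not in df.columns or pd.isna(row[col]):
                values[col] = None
                continue
            try:
                values[col] = float(row[col]) * factor
            except (TypeError, ValueError):
                raise EnergyTableError(
                    f"{path} row {rowno}: non-numeric value {row[col]!r} "
                    f"in column {col}"
                )
        rec = EnergyRecord(
            group_x=str(row["group_x"]),
            group_y=str(row["group_y"]),
            pose_id=str(row["pose_id"]),
            E_complex=values["E_complex"],
            E_X_isolated=values["E_X_isolated"],
            E_Y_isolated=values["E_Y_isolated"],
            E_complex_CP=values["E_complex_CP"],
            E_X_in_complex=values["E_X_in_complex"],
            E_Y_in_complex=values["E_Y_in_complex"],
            extra={c: row[c] for c in extra_cols},
        )
        fingerprint = tuple(values[c] for c in _ENERGY_COLUMNS)
        if rec.key in seen:
            prev_row, prev_fp = seen[rec.key]
            if prev_fp != fingerprint:
                raise EnergyTableError(
                    f"{path}: rows {prev_row} and {rowno} give conflicting "
                    f"energies for {rec.key}"
                )
            continue  # identical duplicate, collapse
        seen[rec.key] = (rowno, fingerprint)
        records.append(rec)
    return records


def write_energy_table(records: Sequence[EnergyRecord], path) -> None:
    """Write records as a kcal/mol CSV; inverse of :func:`read_energy_table`."""
    rows = []
    for r in records:
        row = {
            "group_x": r.group_x, "group_y": r.group_y, "pose_id": r.pose_id,
            "E_complex": r.E_complex, "E_X_isolated": r.E_X_isolated,
            "E_Y_isolated": r.E_Y_isolated, "E_complex_CP": r.E_complex_CP,
            "E_X_in_complex": r.E_X_in_complex,
            "E_Y_in_complex": r.E_Y_in_complex,
        }
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
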