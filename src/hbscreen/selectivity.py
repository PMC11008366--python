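"""Binding matrix, contrast statistics, candidate selection and
pyramidalization analysis.

The central object is the symmetric roster×roster :class:`BindingMatrix` of
best-pose binding energies ``E_XY``.  Selectivity of a pair is measured by
its *binding-energy contrast*:

* binary form  ``E_C = E_XY - (E_XX + E_YY)/2`` — the figure of merit for a
  single complementary pair competing only with its own homo pairs;
* generalized form ``E_C = E_XY - max_Z {E_XZ, E_YZ}`` over a context set of
  letters — the figure of merit inside a multi-letter alphabet, where every
  alternative partner (including homo pairing) competes.

Amino-group planarity is quantified by the pyramidalization angle: the mean
out-of-plane angle of the third N substituent relative to the plane of the
first two, 0° for a fully conjugated planar amine and ≈54.74° for an ideal
tetrahedral one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .endgroups import is_canonical_pair, parse_code
from .energies import EnergyRecord, be_relax, be_rigid, raw_binding_energy
from .errors import MissingPairError, UndefinedCorrelationError
from .geometry import MonomerGeometry

__all__ = [
    "BindingMatrix",
    "PairSummary",
    "CorrelationReport",
    "BandReport",
    "build_matrix",
    "contrast_binary",
    "contrast_generalized",
    "select_candidates",
    "band_report",
    "pyramidalization",
    "correlate_contrast_dihedral",
    "TETRAHEDRAL_ANGLE",
]

#: Out-of-plane angle of an ideal tetrahedral amine, degrees.
TETRAHEDRAL_ANGLE = math.degrees(math.atan(math.sqrt(2.0)))  # 54.7356...


class BindingMatrix:
    """Symmetric matrix of best-pose binding energies over a roster of codes.

    ``provenance[(X, Y)]`` records the winning ``pose_id`` and the energy
    source tag for the unordered pair, so every cell is traceable.
    """

    def __init__(self, roster: Sequence[str], E: np.ndarray,
                 provenance: Dict[Tuple[str, str], Dict[str, str]] = None):
        self.roster = list(roster)
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("roster contains duplicate codes")
        E = np.asarray(E, dtype=float)
        if E.shape != (len(self.roster), len(self.roster)):
            raise ValueError(
                f"matrix shape {E.shape} does not match roster size {len(self.roster)}"
            )
        if not np.allclose(E, E.T, atol=1e-8, equal_nan=True):
            raise ValueError("binding matrix must be symmetric")
        self.E = (E + E.T) / 2.0
        self.provenance = dict(provenance or {})
        self._index = {code: i for i, code in enumerate(self.roster)}

    # -- access -------------------------------------------------------------
    def index(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"unknown end-group code {code!r}")

    def energy(self, x: str, y: str) -> float:
        return float(self.E[self.index(x), self.index(y)])

    def __contains__(self, code: str) -> bool:
        return code in self._index

    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def n_unordered_pairs(self) -> int:
        """Number of unordered cells including the diagonal, n(n+1)/2."""
        return self.n * (self.n + 1) // 2

    def provenance_for(self, x: str, y: str) -> Dict[str, str]:
        return self.provenance.get((x, y)) or self.provenance.get((y, x), {})

    # -- I/O ----------------------------------------------------------------
    def to_square_csv(self, path) -> None:
        df = pd.DataFrame(self.E, index=self.roster, columns=self.roster)
        df.to_csv(path, float_format="%.6f")

    @classmethod
    def from_square_csv(cls, path) -> "BindingMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column rosters differ")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_long_csv(self, path) -> None:
        rows = []
        for i, x in enumerate(self.roster):
            for j in range(i, self.n):
                y = self.roster[j]
                prov = self.provenance_for(x, y)
                rows.append({"X": x, "Y": y, "E": self.E[i, j],
                             "pose_id": prov.get("pose_id", ""),
                             "source": prov.get("source", "")})
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_long_csv(cls, path) -> "BindingMatrix":
        df = pd.read_csv(path)
        for col in ("X", "Y", "E"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        roster = list(dict.fromkeys(list(df["X"]) + list(df["Y"])))
        n = len(roster)
        idx = {c: i for i, c in enumerate(roster)}
        E = np.full((n, n), np.nan)
        prov = {}
        for _, row in df.iterrows():
            i, j = idx[row["X"]], idx[row["Y"]]
            E[i, j] = E[j, i] = float(row["E"])
            if "pose_id" in df.columns and not pd.isna(row.get("pose_id")):
                prov[(row["X"], row["Y"])] = {"pose_id": str(row["pose_id"]),
                                              "source": str(row.get("source", ""))}
        if np.isnan(E).any():
            missing = [(roster[i], roster[j])
                       for i in range(n) for j in range(i, n) if np.isnan(E[i, j])]
            raise MissingPairError(
                f"{path}: {len(missing)} pairs missing (e.g. {missing[:5]})",
                pairs=missing)
        return cls(roster, E, prov)


def build_matrix(records: Iterable[EnergyRecord], energy: str = "raw",
                 roster: Sequence[str] = None,
                 source: str = "table") -> BindingMatrix:
    """Best-pose binding matrix from per-pose energy records.

    ``energy`` selects the column the matrix is built from: ``"raw"``
    (uncorrected dimer energy), ``"be_relax"`` or ``"be_rigid"``.  Every
    roster pair, homo pairs included, must be covered by at least one record;
    missing pairs raise :class:`MissingPairError` listing them.
    """
    extract = {"raw": raw_binding_energy, "be_relax": be_relax,
               "be_rigid": be_rigid}
    if energy not in extract:
        raise ValueError(f"unknown energy column {energy!r}; "
                         f"expected one of {sorted(extract)}")
    fn = extract[energy]

    best: Dict[Tuple[str, str], Tuple[float, str]] = {}
    seen_codes: List[str] = []
    for rec in records:
        for code in (rec.group_x, rec.group_y):
            if code not in seen_codes:
                seen_codes.append(code)
        key = tuple(sorted((rec.group_x, rec.group_y)))
        value = fn(rec)
        incumbent = best.get(key)
        if incumbent is None or value > incumbent[0] or (
                value == incumbent[0] and rec.pose_id < incumbent[1]):
            best[key] = (value, rec.pose_id)

    roster = list(roster) if roster is not None else seen_codes
    n = len(roster)
    missing = []
    E = np.zeros((n, n))
    prov = {}
    for i, x in enumerate(roster):
        for j in range(i, n):
            y = roster[j]
            key = tuple(sorted((x, y)))
            if key not in best:
                missing.append((x, y))
                continue
            value, pose_id = best[key]
            E[i, j] = E[j, i] = value
            prov[(x, y)] = {"pose_id": pose_id, "source": source}
    if missing:
        raise MissingPairError(
            f"{len(missing)} roster pairs have no energy record "
            f"(e.g. {missing[:5]})", pairs=missing)
    return BindingMatrix(roster, E, prov)


# ---------------------------------------------------------------------------
# contrast statistics

def contrast_binary(M: BindingMatrix, x: str, y: str) -> float:
    """``E_XY - (E_XX + E_YY)/2``; zero for a homo pair."""
    return M.energy(x, y) - 0.5 * (M.energy(x, x) + M.energy(y, y))


def contrast_generalized(M: BindingMatrix, x: str, y: str,
                         context: Iterable[str]) -> float:
    """``E_XY - max_Z {E_XZ, E_YZ}`` over alternatives inside ``context``.

    Homo pairings ``E_XX`` and ``E_YY`` count among the alternatives; only
    the pairing of X with Y itself is excluded.  Monotone nonincreasing as
    the context grows.
    """
    context = set(context)
    if not {x, y} <= context:
        raise ValueError("context must contain both letters of the pair")
    alternatives = [M.energy(x, z) for z in context if z != y]
    alternatives += [M.energy(y, z) for z in context if z != x]
    if not alternatives:
        raise ValueError(f"no alternatives for pair ({x}, {y}) in context")
    return M.energy(x, y) - max(alternatives)


@dataclass
class PairSummary:
    """One hetero pair with its selectivity statistics."""

    x: str
    y: str
    E_XY: float
    E_C_binary: float
    E_C_generalized: Optional[float] = None
    context: Optional[Tuple[str, ...]] = None
    canonical: Optional[bool] = None
    class_pair: Optional[str] = None
    mixed: Optional[bool] = None
    angle: Optional[float] = None  # mean pyramidalization angle, degrees

    def to_dict(self) -> dict:
        d = {"X": self.x, "Y": self.y, "E_XY": self.E_XY,
             "E_C_binary": self.E_C_binary}
        for name in ("E_C_generalized", "canonical", "class_pair", "mixed",
                     "angle"):
            value = getattr(self, name)
            if value is not None:
                d[name] = value
        if self.context is not None:
            d["context"] = list(self.context)
        return d


def _pair_summary(M: BindingMatrix, x: str, y: str) -> PairSummary:
    try:
        px, py = parse_code(x).pattern, parse_code(y).pattern
        canonical = is_canonical_pair(px, py)
        class_pair = f"{px.class_label}:{py.class_label}"
        mixed = px.is_mixed or py.is_mixed
    except Exception:
        canonical = class_pair = mixed = None
    return PairSummary(x, y, M.energy(x, y), contrast_binary(M, x, y),
                       canonical=canonical, class_pair=class_pair, mixed=mixed)


def select_candidates(M: BindingMatrix, threshold: float = 5.0) -> List[PairSummary]:
    """Hetero pairs with binary contrast strictly above ``threshold``
    (kcal/mol), sorted by binding energy descending."""
    out = []
    for i, x in enumerate(M.roster):
        for y in M.roster[i + 1:]:
            if contrast_binary(M, x, y) > threshold:
                out.append(_pair_summary(M, x, y))
    out.sort(key=lambda s: (-s.E_XY, s.x, s.y))
    return out


@dataclass
class BandReport:
    """Best candidate per binding-energy band plus the global gap statistic."""

    bands: List[Tuple[float, float, Optional[PairSummary]]]
    max_gap: float

    def to_dict(self) -> dict:
        return {
            "max_gap": self.max_gap,
            "bands": [
                {"lower": lo, "upper": hi,
                 "best": best.to_dict() if best is not None else None}
                for lo, hi, best in self.bands
            ],
        }


def band_report(M: BindingMatrix, candidates: Sequence[PairSummary],
                band_edges: Sequence[float]) -> BandReport:
    """Per band ``[edge_k, edge_{k+1})`` (last band closed), the candidate
    with the highest binary contrast; ``max_gap`` is the largest difference
    between consecutive sorted candidate binding energies."""
    if not candidates:
        raise ValueError("no candidates to report on")
    edges = sorted(band_edges)
    if len(edges) < 2:
        raise ValueError("need at least two band edges")
    bands = []
    for lo, hi in zip(edges, edges[1:]):
        last = hi == edges[-1]
        members = [s for s in candidates
                   if lo <= s.E_XY < hi or (last and s.E_XY == hi)]
        best = max(members, key=lambda s: s.E_C_binary) if members else None
        bands.append((lo, hi, best))
    energies = sorted(s.E_XY for s in candidates)
    max_gap = max((b - a for a, b in zip(energies, energies[1:])), default=0.0)
    return BandReport(bands, max_gap)


# ---------------------------------------------------------------------------
# pyramidalization

_BOND_CUTOFF = 1.75  # angstrom; covers N-H (~1.0) and N-C (~1.47)


def _neighbors(symbols, coords, idx, cutoff):
    d = np.linalg.norm(coords - coords[idx], axis=1)
    nbr = [k for k in range(len(symbols)) if k != idx and d[k] < cutoff]
    return nbr


def pyramidalization(geometry: Union[MonomerGeometry, Tuple],
                     nitrogen_ids: Sequence[int],
                     bond_cutoff: float = _BOND_CUTOFF) -> float:
    """Mean out-of-plane angle (degrees) at the given amino nitrogens.

    For each N the three bonded neighbours are resolved by distance and
    ordered heavy-atoms-first (ring atom, then hydrogens, by index).  The
    angle is between the N→third-substituent bond and the plane through
    (first substituent, N, second substituent): 0° for a planar amine,
    ≈54.74° for ideal tetrahedral geometry.
    """
    if isinstance(geometry, MonomerGeometry):
        symbols, coords = geometry.symbols, geometry.coords
    else:
        symbols, coords = geometry[0], np.asarray(geometry[1], float)
    if not nitrogen_ids:
        raise ValueError("no nitrogen atoms given")
    angles = []
    for idx in nitrogen_ids:
        nbr = _neighbors(symbols, coords, idx, bond_cutoff)
        if len(nbr) != 3:
            raise ValueError(
                f"atom {idx} ({symbols[idx]}) has {len(nbr)} bonded neighbours, "
                "expected exactly 3"
            )
        nbr.sort(key=lambda k: (symbols[k] == "H", k))  # heavy first, then H
        v1, v2, v3 = (coords[k] - coords[idx] for k in nbr)
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            raise ValueError(f"atom {idx}: first two substituents are collinear")
        sin_angle = abs(float(np.dot(v3, normal / norm))) / float(np.linalg.norm(v3))
        angles.append(math.degrees(math.asin(min(1.0, sin_angle))))
    return float(np.mean(angles))


@dataclass
class CorrelationReport:
    """Pearson correlation between contrast and pyramidalization angle."""

    n: int
    r: float

    def to_dict(self) -> dict:
        return {"n": self.n, "r": self.r}


def correlate_contrast_dihedral(contrasts: Sequence[float],
                                angles: Sequence[float]) -> CorrelationReport:
    """Pearson r between binding-energy contrast and mean pyramidalization
    angle; raises when either variable has zero variance."""
    contrasts = np.asarray(contrasts, float)
    angles = np.asarray(angles, float)
    if contrasts.shape != angles.shape:
        raise ValueError("contrast and angle sequences differ in length")
    n = len(contrasts)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(contrasts) == 0 or np.ptp(angles) == 0:
        raise UndefinedCorrelationError(
            "Pearson r undefined: zero variance in contrast or angle")
    r = float(stats.pearsonr(contrasts, angles).statistic)
    return CorrelationReport(n=n, r=r)
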