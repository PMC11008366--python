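"""Packaged 64-group roster and synthetic data generators.

Everything here is generated from code plus a seed — no data blobs.  The
roster emulates a screening assay of 64 nucleobase-analogue end groups: the
named groups recoverable from the screen's vocabulary, five nucleobase
stand-ins, and deterministic filler codes completing the class census
(D, A, DA, DD, AA, DDD, AAA, DDA, DAD and their complements).

Per-group amino planarity follows a documented deterministic rule modelled
on the observed trends: larger aromatic systems conjugate (planarise) amino
groups, additional electron-donating amines pyramidalise them, and pure
acceptors carry no amino group at all (planarity 1 by convention).

:func:`synth_matrix` produces a best-pose surrogate binding matrix over the
roster, optionally overwriting cells to *plant* alphabets with a guaranteed
selectivity margin — the ground truth for recovery tests.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .endgroups import EndGroup, Role, parse_code
from .energies import SurrogateParams, select_best_pose, surrogate_pair_energy
from .errors import InfeasiblePlantError
from .geometry import MonomerGeometry, SiteAnnotation
from .poses import PairPose, enumerate_alignments
from .selectivity import TETRAHEDRAL_ANGLE, BindingMatrix

__all__ = [
    "NAMED_CODES",
    "NUCLEOBASE_CODES",
    "load_roster",
    "planarity_rule",
    "PlantedAlphabet",
    "SyntheticMatrixSpec",
    "surrogate_matrix",
    "synth_matrix",
    "toy_geometry",
]

#: End groups named explicitly in the screening vocabulary.
NAMED_CODES = [
    "HH-hh-p", "HH-pp", "HH-hh", "HH-hp", "HH-h_1", "HH-h_2",
    "HHH-h", "HHH-hh", "HNH-hh",
    "OHO-h-p", "OHO-h_1", "OHO-h_2",
    "NO-h-p", "NO-p", "NNN-hhh", "NNO-hh_1",
]

#: Fixture convention only: shorthand stand-ins for the five nucleobases
#: (Watson-Crick edges read as site rows).  These are roster conventions of
#: this package, not assignments made by any external screen.
NUCLEOBASE_CODES = {
    "adenine": "NH-h-p",   # N1 acceptor, C6-NH2 donor  -> AD
    "guanine": "HHO-h-p",  # N2-H, N1-H donors, O6 acceptor -> DDA
    "cytosine": "ONH-h",   # O2, N3 acceptors, N4-H donor -> AAD
    "thymine": "OHO-h_3",  # O2 acceptor, N3-H donor, O4 acceptor -> ADA
    "uracil": "OHO-h_4",   # same edge as thymine, distinct isomer tag
}

_ROSTER_SIZE = 64


def planarity_rule(code: str) -> float:
    """Deterministic amino-group planarity for a roster code.

    Pure acceptors have no amino group (1.0).  Otherwise planarity grows
    with the size of the aromatic skeleton (conjugation delocalises the
    nitrogen lone pair) and shrinks with every additional donor site
    (electron-donating amines pyramidalise each other), plus a small
    code-keyed deterministic jitter.
    """
    group = parse_code(code)
    n_donors = sum(s.role is Role.DONOR for s in group.pattern)
    if n_donors == 0:
        return 1.0
    n_rings = sum(c in "hp" for c in group.skeleton)
    jitter = (zlib.crc32(code.encode()) % 1000) / 1000.0  # in [0, 1)
    value = 0.45 + 0.18 * n_rings - 0.12 * (n_donors - 1) + 0.10 * jitter
    return float(min(1.0, max(0.0, value)))


def _filler_codes() -> List[str]:
    """Deterministic filler code stream: 1-site, then 2-site, then 3-site."""
    letters = "HNO"
    one = [f"{s}-{sk}" for s in letters for sk in ("h", "p")]
    two_blocks = ["".join(p) for p in itertools.product(letters, repeat=2)]
    two = [f"{s}-{sk}" for s in two_blocks for sk in ("h", "p", "hh", "hp", "h-p")]
    three_blocks = ["".join(p) for p in itertools.product(letters, repeat=3)]
    three = [f"{s}-{sk}" for s in three_blocks for sk in ("hh", "h-p", "hhh", "hh-p")]
    return one, two, three


def load_roster() -> List[EndGroup]:
    """The deterministic 64-group roster, planarity assigned per the rule."""
    codes = list(NAMED_CODES) + list(NUCLEOBASE_CODES.values())
    one, two, three = _filler_codes()
    for code in one:
        if len(codes) >= 27 or code in codes:
            continue
        codes.append(code)
    n_two_target = 47
    for code in two:
        if len(codes) >= n_two_target:
            break
        if code not in codes:
            codes.append(code)
    for code in three:
        if len(codes) >= _ROSTER_SIZE:
            break
        if code not in codes:
            codes.append(code)
    assert len(codes) == _ROSTER_SIZE, f"roster construction yielded {len(codes)}"
    return [parse_code(code, planarity=planarity_rule(code)) for code in codes]


# ---------------------------------------------------------------------------
# surrogate matrices

def surrogate_best(x: EndGroup, y: EndGroup,
                   params: SurrogateParams) -> Tuple[PairPose, float]:
    """Best-scoring register of a pair under the surrogate model."""
    scored = []
    for a in enumerate_alignments(x.pattern, y.pattern):
        scored.append((PairPose(alignment=a),
                       surrogate_pair_energy(x, y, a, params)))
    return select_best_pose(scored)


def surrogate_matrix(groups: Sequence[EndGroup],
                     params: SurrogateParams = SurrogateParams()
                     ) -> BindingMatrix:
    """Best-pose surrogate binding matrix over a roster of end groups."""
    n = len(groups)
    E = np.zeros((n, n))
    prov = {}
    for i in range(n):
        for j in range(i, n):
            pose, energy = surrogate_best(groups[i], groups[j], params)
            E[i, j] = E[j, i] = energy
            prov[(groups[i].code, groups[j].code)] = {
                "pose_id": pose.alignment.pose_id, "source": "surrogate",
            }
    return BindingMatrix([g.code for g in groups], E, prov)


@dataclass(frozen=True)
class PlantedAlphabet:
    """Ground-truth alphabet to imprint on a synthetic matrix.

    ``pairs`` are letter-disjoint code pairs, ``energies`` the binding
    energies to assign to them, and ``margin`` the guaranteed generalized
    contrast: every other interaction among the alphabet's letters (homo
    pairs included) is clamped to ``min(energies) - margin``.  For recovery
    at a search threshold *t*, choose ``margin > t``.
    """

    pairs: Tuple[Tuple[str, str], ...]
    energies: Tuple[float, ...]
    margin: float

    def __post_init__(self):
        object.__setattr__(self, "pairs",
                           tuple(tuple(p) for p in self.pairs))
        object.__setattr__(self, "energies", tuple(float(e) for e in self.energies))

    @property
    def letters(self) -> Tuple[str, ...]:
        return tuple(letter for pair in self.pairs for letter in pair)


@dataclass
class SyntheticMatrixSpec:
    """Recipe for a reproducible synthetic binding matrix."""

    roster: Optional[Sequence[EndGroup]] = None  # default: load_roster()
    params: SurrogateParams = field(default_factory=SurrogateParams)
    planted: Sequence[PlantedAlphabet] = ()
    seed: int = 0


def _validate_planting(planted: Sequence[PlantedAlphabet],
                       roster_codes: Sequence[str]) -> Dict[Tuple[str, str], float]:
    """Resolve all planted cell assignments, failing before generation on
    conflicts (overlapping letters, duplicate cells with different values,
    nonpositive margins)."""
    assignments: Dict[Tuple[str, str], float] = {}

    def assign(u: str, v: str, value: float, what: str):
        cell = tuple(sorted((u, v)))
        if cell in assignments and assignments[cell] != value:
            raise InfeasiblePlantError(
                f"cell {cell} assigned both {assignments[cell]} and {value} "
                f"({what})"
            )
        assignments[cell] = value

    for alphabet in planted:
        if alphabet.margin <= 0:
            raise InfeasiblePlantError(
                f"margin must be positive, got {alphabet.margin}")
        if len(alphabet.energies) != len(alphabet.pairs):
            raise InfeasiblePlantError("one energy per planted pair required")
        letters = alphabet.letters
        if len(set(letters)) != len(letters):
            raise InfeasiblePlantError(
                f"planted pairs share letters: {letters}")
        unknown = [c for c in letters if c not in roster_codes]
        if unknown:
            raise InfeasiblePlantError(f"letters not on roster: {unknown}")
        floor = min(alphabet.energies) - alphabet.margin
        pair_set = {tuple(sorted(p)) for p in alphabet.pairs}
        for pair, energy in zip(alphabet.pairs, alphabet.energies):
            assign(pair[0], pair[1], energy, "planted pair")
        for u in letters:
            for v in letters:
                if u > v or tuple(sorted((u, v))) in pair_set:
                    continue
                assign(u, v, floor, "competition floor")
    return assignments


def synth_matrix(spec: SyntheticMatrixSpec) -> BindingMatrix:
    """Surrogate matrix with planted alphabets imprinted; reproducible per
    ``spec.seed`` (which overrides the surrogate noise seed)."""
    groups = list(spec.roster) if spec.roster is not None else load_roster()
    codes = [g.code for g in groups]
    assignments = _validate_planting(spec.planted, codes)
    params = SurrogateParams(
        P_N=spec.params.P_N, P_O=spec.params.P_O, S=spec.params.S,
        beta=spec.params.beta, R_AA=spec.params.R_AA,
        sigma_noise=spec.params.sigma_noise, seed=spec.seed,
    )
    M = surrogate_matrix(groups, params)
    for (u, v), value in assignments.items():
        i, j = M.index(u), M.index(v)
        M.E[i, j] = M.E[j, i] = value
        M.provenance[(u, v)] = {"pose_id": "planted", "source": "planted"}
    return M


# ---------------------------------------------------------------------------
# toy geometries

_PITCH = 3.0       # angstrom between neighbouring sites
_NH_LEN = 1.01     # donor N-H bond length
_NC_LEN = 1.47     # amino N - ring C
_RING_N_C = 1.34   # pyridinic N - ring C
_KETO_C_O = 1.23   # keto C=O


def toy_geometry(group: EndGroup, pitch: float = _PITCH) -> MonomerGeometry:
    """Planar template geometry in the canonical frame.

    Sites sit on a regular pitch along +x with hydrogen-bond directions
    along +y.  Amino groups are pyramidalised by rotating the second
    (non-bonding) hydrogen out of plane by ``(1 - planarity) * 54.74``
    degrees, so :func:`hbscreen.selectivity.pyramidalization` recovers the
    planted angle exactly.
    """
    theta = math.radians((1.0 - group.planarity) * TETRAHEDRAL_ANGLE)
    symbols: List[str] = []
    coords: List[Tuple[float, float, float]] = []
    sites: List[SiteAnnotation] = []
    amino: List[int] = []
    for k, kind in enumerate(group.pattern):
        x = k * pitch
        if kind.role is Role.DONOR:
            # ring C off the bond axis so (C, N, H1) span the molecular plane
            c = len(symbols)
            symbols.append("C")
            coords.append((x - _NC_LEN * math.sin(math.pi / 3),
                           -_NC_LEN * math.cos(math.pi / 3), 0.0))
            n_idx = len(symbols)
            symbols.append("N"); coords.append((x, 0.0, 0.0))
            h1 = len(symbols)
            symbols.append("H"); coords.append((x, _NH_LEN, 0.0))
            # second amino H, tilted out of plane by theta
            u = np.array([math.sin(2 * math.pi / 3), math.cos(2 * math.pi / 3), 0.0])
            d2 = math.cos(theta) * u + math.sin(theta) * np.array([0.0, 0.0, 1.0])
            h2_pos = np.array([x, 0.0, 0.0]) + _NH_LEN * d2
            symbols.append("H"); coords.append(tuple(h2_pos))
            sites.append(SiteAnnotation(site=k, role=Role.DONOR, anchor=h1,
                                        heavy=n_idx))
            amino.append(n_idx)
        elif kind.flavor.name == "PYRIDINIC_N":
            c = len(symbols)
            symbols.append("C"); coords.append((x, -_RING_N_C, 0.0))
            n_idx = len(symbols)
            symbols.append("N"); coords.append((x, 0.0, 0.0))
            sites.append(SiteAnnotation(site=k, role=Role.ACCEPTOR, anchor=n_idx,
                                        heavy=c))
        else:  # keto oxygen
            c = len(symbols)
            symbols.append("C"); coords.append((x, -_KETO_C_O, 0.0))
            o_idx = len(symbols)
            symbols.append("O"); coords.append((x, 0.0, 0.0))
            sites.append(SiteAnnotation(site=k, role=Role.ACCEPTOR, anchor=o_idx,
                                        heavy=c))
    return MonomerGeometry(symbols, np.asarray(coords, float), sites,
                           comment=group.code, amino_nitrogens=amino)
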