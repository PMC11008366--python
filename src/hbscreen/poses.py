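"""Enumeration of binding registers (poses) of two facing site patterns.

Two end groups approach each other along the hydrogen-bond direction with
their site rows antiparallel.  All initial configurations are generated by
*shifting* the second pattern along the row and optionally *flipping* it;
flipping both molecules is a rigid rotation of the whole complex and is
therefore excluded.

Facing convention: with ``flip=False`` the second pattern is presented
reversed (two molecules facing each other read in opposite directions);
``flip=True`` presents it as written.  A contact is a facing site pair,
counted regardless of its chemistry: for two asymmetric three-site patterns
this yields 10 distinct configurations — 4 with one contact, 4 with two and
2 with three.

Configurations whose chemical contact maps coincide (which happens when
either pattern is palindromic, and always for two single-site patterns) are
deduplicated, keeping the unflipped representative.  Two registers have
identical contact maps exactly when they are related by an internal symmetry
of one of the molecules: reversing a palindromic pattern leaves its physical
site row unchanged, so for a palindromic second pattern the register
``(flip, shift)`` coincides with ``(not flip, shift)``, and for a
palindromic first pattern with ``(not flip, m - n - shift)`` (the flipped
register read after rotating the whole complex).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .endgroups import SiteKind, SitePattern, _as_pattern
from .errors import AlignmentError

__all__ = [
    "Alignment",
    "PairPose",
    "enumerate_alignments",
    "contact_histogram",
    "contact_kinds",
    "mirror",
]


@dataclass(frozen=True)
class Alignment:
    """One shift/flip register of two facing site patterns.

    ``contacts`` is the ordered sequence of ``(i, j)`` index pairs: site
    ``i`` of the first pattern faces site ``j`` of the second.  ``i``
    increases by one along the sequence while, under the facing convention
    (``flip=False``), ``j`` decreases by one.
    """

    flip: bool
    shift: int
    contacts: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if len(self.contacts) < 1:
            raise AlignmentError("an alignment needs at least one contact")
        object.__setattr__(self, "contacts", tuple(map(tuple, self.contacts)))

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def pose_id(self) -> str:
        """Compact identifier, e.g. ``"f0s-2"``."""
        return f"f{int(self.flip)}s{self.shift}"


@dataclass
class PairPose:
    """An alignment optionally realised as a 3D dimer geometry."""

    alignment: Alignment
    geometry: object = None  # DimerGeometry when realised
    gap: float = 2.0
    collided: bool = False  # any intermonomer distance < collision threshold
    energy: Optional[float] = None


def _raw_alignments(m: int, n: int):
    """All 2*(m+n-1) (flip, shift, contacts) registers before dedup."""
    for flip in (False, True):
        for shift in range(-(n - 1), m):
            lo = max(0, shift)
            hi = min(m - 1, shift + n - 1)
            contacts = []
            for i in range(lo, hi + 1):
                k = i - shift  # index into the effective (facing) second pattern
                j = k if flip else (n - 1 - k)
                contacts.append((i, j))
            yield Alignment(flip, shift, tuple(contacts))


def contact_kinds(x, y, a: Alignment) -> List[Tuple[SiteKind, SiteKind]]:
    """Facing ``(site_of_x, site_of_y)`` kinds for every contact of ``a``."""
    x, y = _as_pattern(x), _as_pattern(y)
    kinds = []
    for i, j in a.contacts:
        if not (0 <= i < len(x) and 0 <= j < len(y)):
            raise AlignmentError(
                f"contact ({i},{j}) out of range for patterns of length "
                f"{len(x)} and {len(y)}"
            )
        kinds.append((x[i], y[j]))
    return kinds


def _register_orbit(flip: bool, shift: int, m: int, n: int,
                    pal_x: bool, pal_y: bool):
    """Registers producing a contact map identical to ``(flip, shift)``.

    Reversing a palindromic second pattern maps ``(f, s) -> (not f, s)``;
    reversing a palindromic first pattern maps ``(f, s) -> (not f, m-n-s)``;
    both together give the whole-complex rotation ``(f, s) -> (f, m-n-s)``.
    """
    orbit = {(flip, shift)}
    if pal_y:
        orbit.add((not flip, shift))
    if pal_x:
        orbit.add((not flip, m - n - shift))
    if pal_x and pal_y:
        orbit.add((flip, m - n - shift))
    return orbit


def enumerate_alignments(x, y) -> List[Alignment]:
    """All distinct shift/flip registers of ``x`` facing ``y``.

    Output is ordered by ``(flip, shift)``; duplicates keep the unflipped
    representative.  For two asymmetric patterns of lengths *m*, *n* the
    result has exactly ``2*(m+n-1)`` alignments.
    """
    x, y = _as_pattern(x), _as_pattern(y)
    m, n = len(x), len(y)
    pal_x, pal_y = x.is_palindromic, y.is_palindromic
    seen = set()
    out = []
    for a in _raw_alignments(m, n):
        if (a.flip, a.shift) in seen:
            continue
        seen.update(_register_orbit(a.flip, a.shift, m, n, pal_x, pal_y))
        out.append(a)
    return out


def contact_histogram(alignments: Sequence[Alignment]) -> Dict[int, int]:
    """Map ``n_contacts -> count``; counts partition the input."""
    return dict(Counter(a.n_contacts for a in alignments))


def mirror(a: Alignment, m: int, n: int) -> Alignment:
    """The same pose described from the second molecule's point of view.

    ``a`` aligns an *m*-site pattern against an *n*-site one; the result
    aligns the *n*-site pattern against the *m*-site one and satisfies
    ``contact_kinds(y, x, mirror(a)) == [(b, a) for a, b in contact_kinds(x, y, a)]``.
    """
    shift = (n - m + a.shift) if not a.flip else -a.shift
    contacts = tuple(sorted((j, i) for i, j in a.contacts))
    return Alignment(a.flip, shift, contacts)
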