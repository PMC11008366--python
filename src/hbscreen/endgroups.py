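"""Data model and codec for hydrogen-bonding end groups.

End groups are planar aromatic heterocycles presenting an ordered row of one
to three hydrogen-bond sites.  They are named by shorthand codes: capital
letters for the sites — ``H`` an N-H donor, ``N`` a pyridinic-nitrogen
acceptor, ``O`` a keto-oxygen acceptor — followed by a hyphen and the
aromatic skeleton spelled with ``h`` (hexagonal ring) and ``p`` (pentagonal
ring) letters, e.g. ``"HNH-hh"`` or ``"OHO-h-p"``.  An optional ``_<digits>``
suffix distinguishes structural isomers that share a site pattern.

At the role level a site is a donor (D) or an acceptor (A); two patterns are
*canonically complementary* when one equals the elementwise role complement
of the other, possibly reversed — the analogue of Watson-Crick pairing
(DDA···AAD, DAD···ADA, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Union

from .errors import CapacityError, CodeParseError

__all__ = [
    "Role",
    "Flavor",
    "SiteKind",
    "SitePattern",
    "EndGroup",
    "parse_code",
    "format_code",
    "complement",
    "is_canonical_pair",
]


class Role(str, Enum):
    """Hydrogen-bond role of one site."""

    DONOR = "D"
    ACCEPTOR = "A"


class Flavor(str, Enum):
    """Chemical identity behind a role, as encoded by the site letter."""

    NH_DONOR = "H"
    PYRIDINIC_N = "N"
    KETO_O = "O"


_FLAVOR_ROLE = {
    Flavor.NH_DONOR: Role.DONOR,
    Flavor.PYRIDINIC_N: Role.ACCEPTOR,
    Flavor.KETO_O: Role.ACCEPTOR,
}

# default flavor when only a role is known (e.g. complement of a pattern)
_DEFAULT_FLAVOR = {Role.DONOR: Flavor.NH_DONOR, Role.ACCEPTOR: Flavor.PYRIDINIC_N}


@dataclass(frozen=True)
class SiteKind:
    """One hydrogen-bond site: a role plus its chemical flavor."""

    role: Role
    flavor: Flavor

    def __post_init__(self):
        if _FLAVOR_ROLE[self.flavor] is not self.role:
            raise ValueError(
                f"flavor {self.flavor.name} is inconsistent with role {self.role.name}"
            )

    @classmethod
    def from_letter(cls, letter: str) -> "SiteKind":
        try:
            flavor = Flavor(letter)
        except ValueError:
            raise CodeParseError(f"unknown site letter {letter!r} (expected H, N or O)")
        return cls(_FLAVOR_ROLE[flavor], flavor)

    @classmethod
    def from_role(cls, role: Role) -> "SiteKind":
        return cls(role, _DEFAULT_FLAVOR[role])

    @property
    def letter(self) -> str:
        return self.flavor.value


@dataclass(frozen=True)
class SitePattern:
    """Ordered sequence of 1-3 hydrogen-bond sites."""

    sites: tuple

    def __post_init__(self):
        if not 1 <= len(self.sites) <= 3:
            raise CapacityError(
                f"a pattern must have 1-3 sites, got {len(self.sites)}"
            )
        object.__setattr__(self, "sites", tuple(self.sites))

    @classmethod
    def from_letters(cls, letters: str) -> "SitePattern":
        if len(letters) > 3:
            raise CapacityError(
                f"site block {letters!r} has {len(letters)} letters; at most 3 supported"
            )
        if not letters:
            raise CodeParseError("empty site block")
        return cls(tuple(SiteKind.from_letter(c) for c in letters))

    @classmethod
    def from_roles(cls, roles: Union[str, Iterable[Role]]) -> "SitePattern":
        """Build a pattern from role initials ("DAD") with default flavors."""
        if isinstance(roles, str):
            roles = [Role(c) for c in roles]
        return cls(tuple(SiteKind.from_role(r) for r in roles))

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, i):
        return self.sites[i]

    @property
    def length(self) -> int:
        return len(self.sites)

    @property
    def class_label(self) -> str:
        """Concatenated role initials, e.g. "DAD"."""
        return "".join(s.role.value for s in self.sites)

    @property
    def roles(self) -> tuple:
        return tuple(s.role for s in self.sites)

    @property
    def letters(self) -> str:
        return "".join(s.letter for s in self.sites)

    @property
    def is_palindromic(self) -> bool:
        """Pattern equals its reversal under role *and* flavor."""
        return self.sites == self.sites[::-1]

    @property
    def is_pure(self) -> bool:
        """True when the pattern contains a single role (all-D or all-A)."""
        return len(set(self.roles)) == 1

    @property
    def is_mixed(self) -> bool:
        return not self.is_pure

    def reversed(self) -> "SitePattern":
        return SitePattern(self.sites[::-1])


_CODE_RE = re.compile(r"^(?P<sites>[A-Z]+)-(?P<rest>.+)$")
_VARIANT_RE = re.compile(r"_(?P<digits>\d+)$")


@dataclass(frozen=True)
class EndGroup:
    """A shorthand-coded end group.

    ``planarity`` parameterises how planar the amino (N-H donor) groups are:
    1 means fully conjugated/planar, 0 fully pyramidal.  It feeds the
    surrogate energy model and the toy-geometry generator but never the code
    identity, so it is excluded from equality.
    """

    pattern: SitePattern
    skeleton: str
    variant: str = None  # digits after "_", without the underscore
    planarity: float = field(default=1.0, compare=False)
    geometry_ref: object = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if not self.skeleton:
            raise CodeParseError("empty skeleton")
        if not 0.0 <= self.planarity <= 1.0:
            raise ValueError(f"planarity must lie in [0, 1], got {self.planarity}")

    @property
    def code(self) -> str:
        return format_code(self)

    @property
    def class_label(self) -> str:
        return self.pattern.class_label

    @property
    def n_sites(self) -> int:
        return len(self.pattern)

    def with_planarity(self, planarity: float) -> "EndGroup":
        return EndGroup(self.pattern, self.skeleton, self.variant, planarity,
                        self.geometry_ref)

    def __str__(self) -> str:
        return self.code


def parse_code(code: str, planarity: float = 1.0) -> EndGroup:
    """Parse a shorthand code like ``"OHO-h-p"`` or ``"HH-h_1"``.

    Raises :class:`CodeParseError` naming the offending token on malformed
    input, and :class:`CapacityError` for more than three site letters.
    """
    if not isinstance(code, str):
        raise CodeParseError(f"code must be a string, got {type(code).__name__}")
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise CodeParseError(
            f"malformed code {code!r}: expected SITES-SKELETON[_N], e.g. 'HNH-hh'"
        )
    sites_tok, rest = m.group("sites"), m.group("rest")
    bad = [c for c in sites_tok if c not in "HNO"]
    if bad:
        raise CodeParseError(
            f"malformed code {code!r}: unknown site letter {bad[0]!r} (expected H, N or O)"
        )
    if len(sites_tok) > 3:
        raise CapacityError(
            f"code {code!r} has {len(sites_tok)} site letters; at most 3 supported"
        )
    variant = None
    vm = _VARIANT_RE.search(rest)
    if vm is not None:
        variant = vm.group("digits")
        rest = rest[: vm.start()]
    if not rest:
        raise CodeParseError(f"malformed code {code!r}: empty skeleton")
    for seg in rest.split("-"):
        if not seg:
            raise CodeParseError(f"malformed code {code!r}: empty skeleton segment")
        bad = [c for c in seg if c not in "hp"]
        if bad:
            raise CodeParseError(
                f"malformed code {code!r}: unknown skeleton letter {bad[0]!r} "
                "(expected h or p)"
            )
    return EndGroup(SitePattern.from_letters(sites_tok), rest, variant, planarity)


def format_code(group: EndGroup) -> str:
    """Exact inverse of :func:`parse_code`, hyphens and variant preserved."""
    suffix = f"_{group.variant}" if group.variant is not None else ""
    return f"{group.pattern.letters}-{group.skeleton}{suffix}"


def _as_pattern(x) -> SitePattern:
    if isinstance(x, EndGroup):
        return x.pattern
    if isinstance(x, SitePattern):
        return x
    if isinstance(x, str):
        if set(x) <= {"D", "A"} and x:
            return SitePattern.from_roles(x)
        return parse_code(x).pattern
    raise TypeError(f"cannot interpret {x!r} as a site pattern")


def complement(pattern) -> SitePattern:
    """Role-level complement: D↔A elementwise.

    Flavors in the result are unspecified by the operation; default flavors
    (N-H donor / pyridinic-N acceptor) are assigned.
    """
    pattern = _as_pattern(pattern)
    flipped = [Role.ACCEPTOR if s.role is Role.DONOR else Role.DONOR for s in pattern]
    return SitePattern.from_roles(flipped)


def is_canonical_pair(x, y) -> bool:
    """True when the role patterns are exact complements, possibly reversed.

    Reproduces the canonical classes D···A, DA···AD, DD···AA, DDD···AAA,
    DDA···AAD and DAD···ADA.  Symmetric in its arguments.
    """
    x, y = _as_pattern(x), _as_pattern(y)
    comp = complement(x)
    return y.roles == comp.roles or y.roles == comp.reversed().roles
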