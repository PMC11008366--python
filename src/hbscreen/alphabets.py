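"""Mining of 2-letter and 4-letter alphabets from a binding matrix.

An *alphabet* is a set of letters (end groups) partitioned into mutually
disjoint complementary pairs such that every pair binds within a target
energy window and is selective against every alternative pairing inside the
alphabet: its generalized contrast (``E_XY`` minus the strongest competing
interaction among the alphabet's letters, homo pairs included) exceeds a
threshold.  Letters with a single hydrogen-bond site are excluded by default
because one bond cannot fix the relative orientation of the two molecules.

Energy windows are closed intervals ``[lower, lower + width]``; a sliding
scan moves the window in fixed steps (defaults: width 10 kcal/mol, step 5)
across the observed energy range and counts the alphabets per window.

A brute-force reference implementation (exhaustive enumeration over letter
subsets and perfect matchings) backs the fast search in the test suite.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .endgroups import parse_code
from .errors import CodeParseError
from .selectivity import BindingMatrix, contrast_generalized

__all__ = [
    "WindowSpec",
    "Alphabet",
    "ScanResult",
    "find_2L",
    "find_4L",
    "find_alphabets",
    "scan",
    "brute_force_oracle",
    "classify_alphabet",
]

Pair = FrozenSet[str]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window grid: lower edge (None = from the data), width, step."""

    lower: Optional[float] = None
    width: float = 10.0
    step: float = 5.0

    def __post_init__(self):
        if self.width <= 0 or self.step <= 0:
            raise ValueError("window width and step must be positive")


@dataclass(frozen=True)
class Alphabet:
    """A set of letter-disjoint pairs, each selective inside the alphabet."""

    pairs: FrozenSet[Pair]
    energies: Tuple[float, ...] = field(compare=False, default=())
    contrasts: Tuple[float, ...] = field(compare=False, default=())

    @property
    def letters(self) -> FrozenSet[str]:
        return frozenset(letter for pair in self.pairs for letter in pair)

    @property
    def k(self) -> int:
        return 2 * len(self.pairs)

    def sorted_pairs(self) -> List[Tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self.pairs)

    def to_dict(self) -> dict:
        pairs = self.sorted_pairs()
        d = {"k": self.k, "pairs": [list(p) for p in pairs]}
        if self.energies:
            d["E_XY"] = list(self.energies)
        if self.contrasts:
            d["E_C"] = list(self.contrasts)
        return d


def _n_sites(code: str) -> int:
    return len(parse_code(code).pattern)


def _eligible_letters(M: BindingMatrix, min_sites: int) -> List[str]:
    out = []
    for code in M.roster:
        try:
            n = _n_sites(code)
        except CodeParseError:
            n = min_sites  # unparseable labels are kept; site filter is moot
        if n >= min_sites:
            out.append(code)
    return out


def _as_window(window) -> Tuple[float, float]:
    if isinstance(window, WindowSpec):
        if window.lower is None:
            raise ValueError("WindowSpec.lower must be set for a single window")
        return (window.lower, window.lower + window.width)
    lo, hi = window
    if hi < lo:
        raise ValueError(f"empty window [{lo}, {hi}]")
    return (float(lo), float(hi))


def _in_window(e: float, lo: float, hi: float) -> bool:
    return lo <= e <= hi  # closed on both edges


def _build_alphabet(M: BindingMatrix, pairs: Sequence[Tuple[str, str]],
                    context: FrozenSet[str]) -> Alphabet:
    pairs = [tuple(sorted(p)) for p in pairs]
    pairs.sort()
    energies = tuple(M.energy(x, y) for x, y in pairs)
    contrasts = tuple(contrast_generalized(M, x, y, context) for x, y in pairs)
    return Alphabet(frozenset(frozenset(p) for p in pairs), energies, contrasts)


def find_2L(M: BindingMatrix, window, threshold: float = 5.0,
            min_sites: int = 2, context: str = "letters") -> List[Alphabet]:
    """All selective 2-letter alphabets with ``E_XY`` inside the window.

    ``context`` is the competition scope for the generalized contrast:
    ``"letters"`` (the alphabet's own two letters — a 2L system physically
    contains only those species) or ``"roster"`` (every group on the
    roster competes).
    """
    lo, hi = _as_window(window)
    letters = _eligible_letters(M, min_sites)
    out = []
    for x, y in itertools.combinations(letters, 2):
        if not _in_window(M.energy(x, y), lo, hi):
            continue
        ctx = frozenset(letters if context == "roster" else (x, y))
        if contrast_generalized(M, x, y, ctx) > threshold:
            out.append(_build_alphabet(M, [(x, y)], ctx))
    out.sort(key=lambda a: a.sorted_pairs())
    return out


def find_4L(M: BindingMatrix, window, threshold: float = 5.0,
            min_sites: int = 2, both_in_window: bool = True,
            context: str = "letters") -> List[Alphabet]:
    """All selective 4-letter alphabets (two letter-disjoint pairs).

    Each pair's generalized contrast is evaluated against all four letters.
    By default both pairs must bind inside the window
    (``both_in_window=False`` relaxes this to at least one).
    """
    return find_alphabets(M, window, k=4, threshold=threshold,
                          min_sites=min_sites, both_in_window=both_in_window,
                          context=context)


def find_alphabets(M: BindingMatrix, window, k: int, threshold: float = 5.0,
                   min_sites: int = 2, both_in_window: bool = True,
                   context: str = "letters") -> List[Alphabet]:
    """General even-``k`` alphabet search (k/2 letter-disjoint pairs)."""
    if k < 2 or k % 2:
        raise ValueError("k must be a positive even number")
    if k == 2:
        return find_2L(M, window, threshold, min_sites, context)
    lo, hi = _as_window(window)
    letters = _eligible_letters(M, min_sites)
    if not both_in_window:
        out = _relaxed_window_search(M, (lo, hi), k, threshold, min_sites,
                                     context, letters)
        out.sort(key=lambda a: a.sorted_pairs())
        return out
    in_window = [
        (x, y) for x, y in itertools.combinations(letters, 2)
        if _in_window(M.energy(x, y), lo, hi)
    ]
    out = []
    seen = set()
    for combo in itertools.combinations(in_window, k // 2):
        used: set = set()
        ok = True
        for x, y in combo:
            if x in used or y in used:
                ok = False
                break
            used.update((x, y))
        if not ok:
            continue
        ctx = frozenset(letters if context == "roster" else used)
        if all(contrast_generalized(M, x, y, ctx) > threshold for x, y in combo):
            alphabet = _build_alphabet(M, combo, ctx)
            if alphabet.pairs not in seen:
                seen.add(alphabet.pairs)
                out.append(alphabet)
    out.sort(key=lambda a: a.sorted_pairs())
    return out


def _relaxed_window_search(M, window, k, threshold, min_sites, context,
                           letters) -> List[Alphabet]:
    """Variant where only one pair needs to bind inside the window."""
    lo, hi = window
    all_pairs = list(itertools.combinations(letters, 2))
    out = []
    seen = set()
    for combo in itertools.combinations(all_pairs, k // 2):
        used: set = set()
        ok = True
        for x, y in combo:
            if x in used or y in used:
                ok = False
                break
            used.update((x, y))
        if not ok:
            continue
        if not any(_in_window(M.energy(x, y), lo, hi) for x, y in combo):
            continue
        ctx = frozenset(letters if context == "roster" else used)
        if all(contrast_generalized(M, x, y, ctx) > threshold for x, y in combo):
            alphabet = _build_alphabet(M, combo, ctx)
            if alphabet.pairs not in seen:
                seen.add(alphabet.pairs)
                out.append(alphabet)
    return out


# ---------------------------------------------------------------------------
# brute-force reference

def _perfect_matchings(letters: Tuple[str, ...]):
    """All perfect matchings of an even-sized letter tuple."""
    if not letters:
        yield ()
        return
    first, rest = letters[0], letters[1:]
    for i, partner in enumerate(rest):
        remainder = rest[:i] + rest[i + 1:]
        for sub in _perfect_matchings(remainder):
            yield ((first, partner),) + sub


def brute_force_oracle(M: BindingMatrix, window, threshold: float, k: int,
                       min_sites: int = 2, both_in_window: bool = True,
                       context: str = "letters") -> List[Alphabet]:
    """Exhaustive enumeration over all letter subsets and pairings.

    Same contract as :func:`find_2L` / :func:`find_4L`; intended as ground
    truth for rosters up to a few dozen groups.
    """
    if k < 2 or k % 2:
        raise ValueError("k must be a positive even number")
    lo, hi = _as_window(window)
    letters = _eligible_letters(M, min_sites)
    out = []
    seen = set()
    for subset in itertools.combinations(letters, k):
        ctx = frozenset(letters if context == "roster" else subset)
        for matching in _perfect_matchings(subset):
            flags = [_in_window(M.energy(x, y), lo, hi) for x, y in matching]
            if both_in_window:
                if not all(flags):
                    continue
            elif not any(flags):
                continue
            if all(contrast_generalized(M, x, y, ctx) > threshold
                   for x, y in matching):
                alphabet = _build_alphabet(M, matching, ctx)
                if alphabet.pairs not in seen:
                    seen.add(alphabet.pairs)
                    out.append(alphabet)
    out.sort(key=lambda a: a.sorted_pairs())
    return out


# ---------------------------------------------------------------------------
# sliding-window scan

@dataclass
class WindowResult:
    lower: float
    upper: float
    counts: Dict[int, int]
    alphabets: Dict[int, List[Alphabet]]

    def to_dict(self) -> dict:
        return {
            "window": [self.lower, self.upper],
            "counts": {f"{k}L": v for k, v in sorted(self.counts.items())},
            "alphabets": {
                f"{k}L": [a.to_dict() for a in alphas]
                for k, alphas in sorted(self.alphabets.items())
            },
        }


@dataclass
class ScanResult:
    spec: WindowSpec
    threshold: float
    windows: List[WindowResult]

    def counts_table(self):
        import pandas as pd

        rows = []
        for w in self.windows:
            row = {"lower": w.lower, "upper": w.upper}
            row.update({f"n_{k}L": v for k, v in sorted(w.counts.items())})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "width": self.spec.width,
            "step": self.spec.step,
            "threshold": self.threshold,
            "windows": [w.to_dict() for w in self.windows],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def scan(M: BindingMatrix, spec: WindowSpec = WindowSpec(),
         threshold: float = 5.0, ks: Sequence[int] = (2, 4),
         min_sites: int = 2, context: str = "letters") -> ScanResult:
    """Count alphabets of each size in sliding windows across the observed
    hetero-pair energy range.  Deterministic."""
    letters = _eligible_letters(M, min_sites)
    energies = [M.energy(x, y)
                for x, y in itertools.combinations(letters, 2)]
    windows: List[WindowResult] = []
    if energies:
        e_min, e_max = min(energies), max(energies)
        if spec.lower is not None:
            start = spec.lower
        else:
            start = spec.step * math.floor(e_min / spec.step)
        lower = start
        while lower <= e_max:
            counts, alphas = {}, {}
            for k in ks:
                found = find_alphabets(M, (lower, lower + spec.width), k,
                                       threshold, min_sites, context=context)
                counts[k] = len(found)
                alphas[k] = found
            windows.append(WindowResult(lower, lower + spec.width, counts, alphas))
            lower += spec.step
    return ScanResult(spec, threshold, windows)


# ---------------------------------------------------------------------------
# composition labels

def classify_alphabet(a: Alphabet) -> str:
    """Composition label: each pair is *pure* (both patterns single-role) or
    *mixed* (a pattern containing both roles); e.g. ``"pure+mixed"``."""
    labels = []
    for pair in a.sorted_pairs():
        patterns = [parse_code(code).pattern for code in pair]
        labels.append("pure" if all(p.is_pure for p in patterns) else "mixed")
    labels.sort(key=lambda s: s != "pure")  # pure first
    return "+".join(labels)
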