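"""The three dynamic 3D curves of a characteristic sequence.

Each of the three chemical classifications of bases — amino/keto
(M-K), purine/pyrimidine (R-Y), weak/strong H-bond (W-S) — yields a
map from characteristic-sequence positions to 3D points.  For position
``i`` of a length-``n`` sequence, with ``t = i / (n + 1)``:

* x = +t for unpaired symbols, −t for primed symbols;
* y = +sqrt(1 − t²) for the first-listed (positive) set of the
  classification, −sqrt(1 − t²) for the second;
* z = running total of the two symbols in the point's group-set,
  counted over positions 1..i inclusive.

The X-Y projection of every point therefore lies on the unit circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import CharacteristicSequence

_PRIMES = ("A'", "G'", "C'", "U'")
SYMBOL_ORDER = ("A", "G", "C", "U") + _PRIMES


@dataclass(frozen=True)
class GroupScheme:
    """The four symbol group-sets of one map.

    Group indices: 1 = positive unpaired, 2 = negative unpaired,
    3 = positive paired, 4 = negative paired.  The four sets partition
    the 8-symbol alphabet.
    """

    map_index: int
    positive_unpaired: frozenset[str]
    negative_unpaired: frozenset[str]
    positive_paired: frozenset[str]
    negative_paired: frozenset[str]

    def __post_init__(self) -> None:
        sets = (self.positive_unpaired, self.negative_unpaired, self.positive_paired, self.negative_paired)
        union = frozenset().union(*sets)
        if union != frozenset(SYMBOL_ORDER) or sum(len(s) for s in sets) != 8:
            raise ValueError(f"group-sets of map {self.map_index} do not partition the alphabet")

    @property
    def groups(self) -> tuple[frozenset[str], ...]:
        return (self.positive_unpaired, self.negative_unpaired, self.positive_paired, self.negative_paired)

    def group_of(self, symbol: str) -> int:
        """1-based group index of ``symbol``."""
        for j, grp in enumerate(self.groups, start=1):
            if symbol in grp:
                return j
        raise KeyError(symbol)


def _scheme(k: int, pos: str, neg: str) -> GroupScheme:
    return GroupScheme(
        map_index=k,
        positive_unpaired=frozenset(pos),
        negative_unpaired=frozenset(neg),
        positive_paired=frozenset(b + "'" for b in pos),
        negative_paired=frozenset(b + "'" for b in neg),
    )


#: map 1: amino M={A,C} / keto K={G,U}; map 2: purine R={A,G} /
#: pyrimidine Y={C,U}; map 3: weak W={A,U} / strong S={C,G}
SCHEMES: dict[int, GroupScheme] = {
    1: _scheme(1, "AC", "GU"),
    2: _scheme(2, "AG", "CU"),
    3: _scheme(3, "AU", "CG"),
}

MAP_NAMES = {1: "M-K", 2: "R-Y", 3: "W-S"}


@dataclass(frozen=True)
class CumulativeCounts:
    """Running totals of the 8 symbols over prefixes of the sequence.

    ``totals[s][i - 1]`` is the number of occurrences of symbol ``s``
    in positions 1..i.
    """

    n: int
    totals: dict[str, tuple[int, ...]]

    def at(self, symbol: str, i: int) -> int:
        return self.totals[symbol][i - 1]


def cumulative_counts(cs: CharacteristicSequence) -> CumulativeCounts:
    """Streaming per-symbol occurrence totals of ``cs``."""
    n = len(cs)
    index = {s: j for j, s in enumerate(SYMBOL_ORDER)}
    onehot = np.zeros((n, 8), dtype=np.int64)
    for i, sym in enumerate(cs.symbols):
        onehot[i, index[sym]] = 1
    cum = onehot.cumsum(axis=0)
    return CumulativeCounts(n=n, totals={s: tuple(cum[:, j].tolist()) for s, j in index.items()})


@dataclass(frozen=True)
class Curve3D:
    """Ordered 3D points of one map, connected in sequence order."""

    map_index: int
    points: np.ndarray  # shape (n, 3), float
    group_of_point: tuple[int, ...]  # 1..4 per point

    def __len__(self) -> int:
        return len(self.group_of_point)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


def map_curve(cs: CharacteristicSequence, k: int) -> Curve3D:
    """Build the 3D curve of map ``k`` (1 = M-K, 2 = R-Y, 3 = W-S)."""
    if k not in SCHEMES:
        raise ValueError(f"invalid map index {k}; expected 1, 2, or 3")
    scheme = SCHEMES[k]
    counts = cumulative_counts(cs)
    n = len(cs)
    points = np.empty((n, 3), dtype=float)
    groups = []
    for i, sym in enumerate(cs.symbols, start=1):
        t = i / (n + 1)
        radicand = 1.0 - t * t
        assert radicand > 0.0  # t in (0, 1) by construction
        j = scheme.group_of(sym)
        group_set = scheme.groups[j - 1]
        x = -t if sym.endswith("'") else t
        y = math.sqrt(radicand) if j in (1, 3) else -math.sqrt(radicand)
        z = sum(counts.at(s, i) for s in group_set)
        points[i - 1] = (x, y, z)
        groups.append(j)
    return Curve3D(map_index=k, points=points, group_of_point=tuple(groups))


def all_curves(cs: CharacteristicSequence) -> tuple[Curve3D, Curve3D, Curve3D]:
    """The M-K, R-Y and W-S curves of ``cs``, in that order."""
    return (map_curve(cs, 1), map_curve(cs, 2), map_curve(cs, 3))
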