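"""Random valid secondary structures and family-structured datasets.

Pairing is greedy and purely combinatorial (complementary A-U, G-C,
G-U partners, non-crossing unless pseudoknots are requested); no
thermodynamics.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structure_io import SecondaryStructure

_BASES = ("A", "C", "G", "U")
_COMPLEMENTS = {"A": ("U",), "U": ("A", "G"), "G": ("C", "U"), "C": ("G",)}
_PAIR_TYPES = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one random structure draw."""

    n: int
    pair_fraction: float = 0.0
    allow_pseudoknots: bool = False
    gc_bias: dict[str, float] = field(default_factory=lambda: {b: 1.0 for b in _BASES})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.pair_fraction <= 1.0:
            raise ValueError("pair_fraction must lie in [0, 1]")
        if set(self.gc_bias) != set(_BASES) or any(w <= 0 for w in self.gc_bias.values()):
            raise ValueError("gc_bias must give a positive weight to each of A, C, G, U")


def _weights(cfg: SimulationConfig) -> np.ndarray:
    w = np.array([cfg.gc_bias[b] for b in _BASES], dtype=float)
    return w / w.sum()


def _noncrossing_matching(positions: list[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random non-crossing perfect matching of sorted positions.

    Equivalent to a random balanced bracket string: at each step open a
    new pair or close the innermost open one, with forced moves at the
    boundaries.
    """
    m = len(positions) // 2
    stack: list[int] = []
    pairs = []
    opens_left = m
    for pos in positions:
        must_open = not stack
        must_close = opens_left == 0
        if must_open or (not must_close and rng.random() < 0.5):
            stack.append(pos)
            opens_left -= 1
        else:
            pairs.append((stack.pop(), pos))
    assert not stack and opens_left == 0
    return pairs


def _crossing_matching(positions: list[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    perm = rng.permutation(len(positions))
    it = iter(perm)
    pairs = []
    for a, b in zip(it, it):
        i, j = positions[a], positions[b]
        pairs.append((min(i, j), max(i, j)))
    return pairs


def random_structure(cfg: SimulationConfig, name: str = "") -> SecondaryStructure:
    """Draw one valid structure; fully reproducible from ``cfg.seed``.

    The realized paired fraction is within 1/n of ``pair_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pairs = round(cfg.pair_fraction * cfg.n / 2.0)
    if cfg.pair_fraction > 0 and cfg.n < 2:
        raise ValueError(f"cannot pair bases with n = {cfg.n}")
    probs = _weights(cfg)
    bases = list(rng.choice(_BASES, size=cfg.n, p=probs))

    pairs: list[tuple[int, int]] = []
    if n_pairs:
        chosen = sorted(rng.choice(cfg.n, size=2 * n_pairs, replace=False) + 1)
        if cfg.allow_pseudoknots:
            pairs = _crossing_matching([int(p) for p in chosen], rng)
        else:
            pairs = _noncrossing_matching([int(p) for p in chosen], rng)
        for i, j in pairs:
            left, right = _draw_pair(rng, probs)
            bases[i - 1], bases[j - 1] = left, right

    return SecondaryStructure(
        name=name or f"sim_n{cfg.n}_s{cfg.seed}",
        sequence="".join(bases),
        pairs=frozenset(pairs),
    )


def _draw_pair(rng: np.random.Generator, probs: np.ndarray) -> tuple[str, str]:
    weights = np.array([probs[_BASES.index(a)] * probs[_BASES.index(b)] for a, b in _PAIR_TYPES])
    idx = rng.choice(len(_PAIR_TYPES), p=weights / weights.sum())
    return _PAIR_TYPES[idx]


def mutate_structure(
    parent: SecondaryStructure,
    divergence: float,
    rng: np.random.Generator,
    name: str,
) -> SecondaryStructure:
    """Point-mutate bases and toggle pairs at the given per-position rate."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    bases = list(parent.sequence)
    partner = {}
    for i, j in parent.pairs:
        partner[i] = j
        partner[j] = i
    pairs = set(parent.pairs)
    visited: set[int] = set()
    for pos in range(1, len(bases) + 1):
        if pos in visited or rng.random() >= divergence:
            continue
        if pos in partner:
            j = partner[pos]
            visited.add(j)
            i, j = min(pos, j), max(pos, j)
            if rng.random() < 0.5:  # toggle the pair off, bases retained
                pairs.discard((i, j))
            else:  # substitute with a random complementary pair
                left, right = _PAIR_TYPES[rng.integers(len(_PAIR_TYPES))]
                bases[i - 1], bases[j - 1] = left, right
        else:
            alternatives = [b for b in _BASES if b != bases[pos - 1]]
            bases[pos - 1] = alternatives[rng.integers(3)]
    return SecondaryStructure(name=name, sequence="".join(bases), pairs=frozenset(pairs))


def family_dataset(
    k_families: int,
    per_family: int,
    divergence: float,
    seed: int,
    *,
    n: int = 120,
    pair_fraction: float = 0.5,
    allow_pseudoknots: bool = False,
) -> tuple[list[SecondaryStructure], dict[str, str]]:
    """Random families of point-mutated copies of per-family ancestors.

    Each family's ancestor draws its own base-composition weights and a
    pairing level jittered around ``pair_fraction``, so families carry
    distinct compositional identities while members differ only by the
    mutation rate.  Returns the structures plus a label → family table
    suitable for :func:`rnacurve.tree.cluster_purity`.
    """
    if k_families < 2:
        raise ValueError("k_families must be >= 2")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    structures: list[SecondaryStructure] = []
    families: dict[str, str] = {}
    for f in range(1, k_families + 1):
        fam = f"fam{f:02d}"
        weights = rng.dirichlet(np.full(4, 1.5))
        fam_pf = float(np.clip(pair_fraction + rng.uniform(-0.2, 0.2), 0.0, 1.0))
        ancestor_cfg = SimulationConfig(
            n=n,
            pair_fraction=fam_pf,
            allow_pseudoknots=allow_pseudoknots,
            gc_bias={b: float(w) + 1e-3 for b, w in zip(_BASES, weights)},
            seed=int(rng.integers(2**31)),
        )
        ancestor = random_structure(ancestor_cfg, name=f"{fam}_anc")
        for m in range(1, per_family + 1):
            label = f"{fam}_m{m}"
            member = mutate_structure(replace(ancestor, name=label), divergence, rng, label)
            structures.append(member)
            families[label] = fam
    return structures, families
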