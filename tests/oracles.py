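"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's curve/descriptor code paths:
coordinates and the 36 component sums are recomputed here directly from
their definitions with plain Python loops.
"""

from __future__ import annotations

import math

# group-set pairs per map, in component order j = 1..4
_GROUPS = {
    1: [("A", "C"), ("G", "U"), ("A'", "C'"), ("G'", "U'")],
    2: [("A", "G"), ("C", "U"), ("A'", "G'"), ("C'", "U'")],
    3: [("A", "U"), ("C", "G"), ("A'", "U'"), ("C'", "G'")],
}


def brute_force_point(symbols: tuple[str, ...], k: int, i: int) -> tuple[float, float, float]:
    """Coordinates of position ``i`` (1-based) of map ``k``, from scratch."""
    n = len(symbols)
    sym = symbols[i - 1]
    t = i / (n + 1)
    for j, (s1, s2) in enumerate(_GROUPS[k], start=1):
        if sym in (s1, s2):
            x = -t if sym.endswith("'") else t
            y = math.sqrt(1 - t * t) * (1 if j in (1, 3) else -1)
            z = sum(1 for m in range(i) if symbols[m] in (s1, s2))
            return (x, y, z)
    raise AssertionError(f"symbol {sym!r} not in any group of map {k}")


def brute_force_descriptor(symbols: tuple[str, ...]) -> list[float]:
    """All 36 components via a direct double loop over the definitions."""
    n = len(symbols)
    out = []
    for k in (1, 2, 3):
        for j, (s1, s2) in enumerate(_GROUPS[k], start=1):
            sx = sy = sz = 0.0
            for i in range(1, n + 1):
                if symbols[i - 1] in (s1, s2):
                    x, y, z = brute_force_point(symbols, k, i)
                    sx += x
                    sy += y
                    sz += z
            out.extend([sx / n, sy / n, sz / n])
    return out


def brute_force_quotient(u: list[float], v: list[float]) -> float:
    dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))
    if dist == 0:
        return 0.0
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return dist / (dot / (nu * nv))
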