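"""Independent brute-force oracles used by the test suite.

These deliberately avoid dynamic programming: alignments are enumerated as
explicit move sequences (match / gap-in-template / gap-in-query) so the
aligner's recurrences can be checked against an exhaustive search on small
profiles.
"""

from __future__ import annotations

import math


def brute_force_best_score(S, qopen, qext, topen, text, mode: str) -> float:
    """Maximum alignment score by exhaustive enumeration of move sequences.

    ``S`` is the (n, m) column-score matrix; ``qopen``/``qext`` are the
    penalties charged when query position i sits opposite a gap, and
    ``topen``/``text`` when template position j does.  Affine charging: a
    gap move following a different move type pays open, a repeat pays
    extend, always at the consumed position.
    """
    n, m = S.shape
    best = -math.inf

    record_local = mode == "local"

    def rec(i: int, j: int, prev: str | None, score: float) -> None:
        nonlocal best
        if mode == "global":
            if i == n and j == m and score > best:
                best = score
        elif mode == "gloloc":
            if j == m and score > best:  # remaining query flank is free
                best = score
        elif record_local:
            if score > best:
                best = score
        if i < n:
            pen = qext[i] if prev == "X" else qopen[i]
            rec(i + 1, j, "X", score - pen)
        if j < m:
            pen = text[j] if prev == "Y" else topen[j]
            rec(i, j + 1, "Y", score - pen)
        if i < n and j < m:
            rec(i + 1, j + 1, "M", score + S[i, j])

    if mode == "global":
        rec(0, 0, None, 0.0)
    elif mode == "gloloc":
        for i0 in range(n + 1):
            rec(i0, 0, None, 0.0)
    elif mode == "local":
        best = 0.0  # the empty alignment
        for i0 in range(n):
            for j0 in range(m):
                rec(i0, j0, None, 0.0)
    else:
        raise ValueError(mode)
    return best


def brute_force_correlation(scores, d: int) -> float:
    """Correlation score by explicit enumeration of in-window index pairs."""
    total = 0.0
    L = len(scores)
    for l in range(L):
        for j in range(1, d + 1):
            if l + j < L:
                total += scores[l] * scores[l + j]
    return total


def two_sphere_exposed_area_grid(r1: float, r2: float, dist: float, n_theta: int = 2000) -> float:
    """Exposed area of sphere 1 by dense latitude-band numerical integration.

    Sphere 2 sits on the +z axis at ``dist``; by symmetry each latitude band
    of sphere 1 is entirely inside or outside sphere 2, so integrating band
    areas over a fine theta grid converges to the exposed area.
    """
    total = 0.0
    for k in range(n_theta):
        theta = math.pi * (k + 0.5) / n_theta
        band = 2.0 * math.pi * r1**2 * math.sin(theta) * (math.pi / n_theta)
        z = r1 * math.cos(theta)
        rho = r1 * math.sin(theta)
        if rho**2 + (z - dist) ** 2 >= r2**2:
            total += band
    return total


def two_sphere_exposed_area(r1: float, r2: float, dist: float) -> tuple[float, float]:
    """Closed-form exposed areas of two overlapping spheres (sphere radii
    already include the probe).  Returns (area1, area2)."""
    a1 = 4.0 * math.pi * r1**2
    a2 = 4.0 * math.pi * r2**2
    if dist >= r1 + r2:
        return a1, a2
    # spherical-cap heights buried on each sphere
    x1 = (dist**2 + r1**2 - r2**2) / (2.0 * dist)
    h1 = r1 - x1
    h2 = r2 - (dist - x1)
    return a1 - 2.0 * math.pi * r1 * h1, a2 - 2.0 * math.pi * r2 * h2
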