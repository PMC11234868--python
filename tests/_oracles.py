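"""Independent oracles used by the tests.

These deliberately avoid the package's own group/graph machinery: rotations
are built from explicit rotation matrices and orbits by brute-force set
closure, and regression uses the closed-form normal equations.
"""

from __future__ import annotations

import itertools

import numpy as np


def octahedron_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the octahedron as signed permutation matrices."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    assert len(mats) == 24
    return mats


def axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def tbp_rotations() -> list[np.ndarray]:
    """The 6 proper rotations (D3) of the trigonal bipyramid."""
    c, s = -0.5, np.sqrt(3.0) / 2.0
    eq = [np.array([1.0, 0, 0]), np.array([c, s, 0]), np.array([c, -s, 0])]
    mats = [axis_rotation([0, 0, 1], a) for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)]
    mats += [axis_rotation(v, np.pi) for v in eq]
    assert len(mats) == 6
    return mats


def site_permutations(vectors: np.ndarray, rotations: list[np.ndarray]) -> set[tuple[int, ...]]:
    """Each rotation as the site permutation it induces (must map sites to sites)."""
    perms = set()
    for rot in rotations:
        perm = []
        for v in vectors:
            img = rot @ v
            hits = [j for j, w in enumerate(vectors) if np.allclose(img, w, atol=1e-8)]
            assert len(hits) == 1
            perm.append(hits[0])
        perms.add(tuple(perm))
    return perms


def count_distinct_placements(
    vectors: np.ndarray, rotations: list[np.ndarray], colors: list[str]
) -> int:
    """Brute force: all colorings of the sites, merged into rotation orbits."""
    perms = site_permutations(vectors, rotations)
    assignments = set(itertools.permutations(colors))
    orbits = set()
    for assignment in assignments:
        orbit = frozenset(
            tuple(assignment[perm[i]] for i in range(len(assignment))) for perm in perms
        )
        orbits.add(orbit)
    return len(orbits)


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least squares: slope, intercept, R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    syy = float(((y - ym) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / syy if syy > 0 else 1.0
    return slope, intercept, r2
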