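"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's Kabsch/Lance-Williams code paths:
the rotation oracle scans a dense rotation grid, the clustering oracle
re-averages all inter-cluster pairs from scratch at every merge, and the
two-sphere SASA oracle is the closed-form spherical-cap formula.
"""

import numpy as np


def fibonacci_axes(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


def rotation_grid(n_axes: int, angle_step_deg: float):
    """Rotation-matrix bank over Fibonacci axes x regular angles, plus the
    identity; returns (matrices, worst-case angular resolution in rad)."""
    axes = fibonacci_axes(n_axes)
    angles = np.deg2rad(np.arange(angle_step_deg, 180.0 + 1e-9,
                                  angle_step_deg))
    ax = np.repeat(axes, len(angles), axis=0)
    an = np.tile(angles, n_axes)
    c, s = np.cos(an), np.sin(an)
    x, y, z = ax[:, 0], ax[:, 1], ax[:, 2]
    m = np.empty((len(an), 3, 3))
    m[:, 0, 0] = c + x * x * (1 - c)
    m[:, 0, 1] = x * y * (1 - c) - z * s
    m[:, 0, 2] = x * z * (1 - c) + y * s
    m[:, 1, 0] = y * x * (1 - c) + z * s
    m[:, 1, 1] = c + y * y * (1 - c)
    m[:, 1, 2] = y * z * (1 - c) - x * s
    m[:, 2, 0] = z * x * (1 - c) - y * s
    m[:, 2, 1] = z * y * (1 - c) + x * s
    m[:, 2, 2] = c + z * z * (1 - c)
    m = np.concatenate([np.eye(3)[None], m])
    # worst-case rotation distance to the nearest grid point: axis spacing
    # (~ 2 sqrt(pi/n) for a Fibonacci sphere) plus half the angle step
    resolution = 2.0 * np.sqrt(np.pi / n_axes) \
        + 0.5 * np.deg2rad(angle_step_deg)
    return m, resolution


def grid_min_rmsd(mobile: np.ndarray, target: np.ndarray,
                  rotations: np.ndarray, chunk: int = 300_000) -> float:
    """Minimum RMSD over the rotation grid after centroid superposition."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    best = np.inf
    for start in range(0, len(rotations), chunk):
        r = rotations[start:start + chunk]
        rotated = np.einsum("rij,aj->rai", r, a)
        msd = np.mean(np.sum((rotated - b[None]) ** 2, axis=2), axis=1)
        best = min(best, float(msd.min()))
    return float(np.sqrt(best))


def naive_average_linkage(dist: np.ndarray, cutoff: float):
    """Exhaustive agglomeration: inter-cluster averages recomputed from the
    raw matrix at every step; ties to the smallest index pair.  Returns a
    set of frozensets (the partition)."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(np.mean([dist[a, b] for a in clusters[i]
                                   for b in clusters[j]]))
                key = (min(clusters[i][0], clusters[j][0]),
                       max(clusters[i][0], clusters[j][0]))
                if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12
                                          and best is not None
                                          and key < best[2]):
                    best = (i, j, key)
                    best_d = d
        if best_d > cutoff:
            break
        i, j, _ = best
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return {frozenset(c) for c in clusters}


def two_sphere_sasa(r1: float, r2: float, d: float) -> float:
    """Accessible area of expanded sphere 1 partially buried by sphere 2
    (closed-form spherical cap)."""
    if d >= r1 + r2:
        return 4.0 * np.pi * r1 ** 2
    x1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    cap_height = r1 - x1
    return 4.0 * np.pi * r1 ** 2 - 2.0 * np.pi * r1 * cap_height
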