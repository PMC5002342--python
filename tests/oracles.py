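"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a deliberately different route from the
implementation under test: fixed-point sweeping instead of a heap front,
subset enumeration + np.roots instead of the sorted-prefix quadratic,
all-pairs distances instead of KD-trees, explicit triple loops instead of
vectorized gathers.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import cdist


def upwind_candidates(tmins, spacings, f):
    """All causal Godunov roots for one voxel, via subset enumeration."""
    axes = [(t, h) for t, h in zip(tmins, spacings) if np.isfinite(t)]
    cands = []
    for r in range(1, len(axes) + 1):
        for subset in itertools.combinations(axes, r):
            a = sum(1.0 / h**2 for _, h in subset)
            b = sum(-2.0 * t / h**2 for t, h in subset)
            c = sum(t**2 / h**2 for t, h in subset) - 1.0 / f**2
            roots = np.roots([a, b, c])
            for root in roots:
                if abs(root.imag) < 1e-12 and root.real >= max(t for t, _ in subset) - 1e-14:
                    cands.append(root.real)
    return cands


def fixed_point_eikonal(speed: np.ndarray, spacing, seeds, tol=1e-14, max_sweeps=2000):
    """Gauss-Seidel fixed-point solution of the first-order upwind Eikonal
    discretization (no front, no heap): sweep until no update exceeds tol."""
    F = np.asarray(speed, dtype=float)
    shape = F.shape
    T = np.full(shape, np.inf)
    for s in seeds:
        T[tuple(s)] = 0.0
    seed_set = {tuple(s) for s in seeds}
    orders = list(itertools.product([1, -1], repeat=3))
    for _ in range(max_sweeps):
        delta = 0.0
        for ox, oy, oz in orders:
            xs = range(shape[0])[::ox]
            ys = range(shape[1])[::oy]
            zs = range(shape[2])[::oz]
            for x in xs:
                for y in ys:
                    for z in zs:
                        if (x, y, z) in seed_set:
                            continue
                        tmins = []
                        for ax, n in enumerate(shape):
                            vals = []
                            for d in (-1, 1):
                                q = [x, y, z]
                                q[ax] += d
                                if 0 <= q[ax] < n:
                                    vals.append(T[tuple(q)])
                            tmins.append(min(vals) if vals else np.inf)
                        cands = upwind_candidates(tmins, spacing, F[x, y, z])
                        if cands:
                            new = min(cands)
                            if new < T[x, y, z]:
                                delta = max(delta, T[x, y, z] - new)
                                T[x, y, z] = new
        if delta <= tol:
            break
    return T


def dijkstra6(speed: np.ndarray, spacing, seeds):
    """6-connected shortest-path times, edge cost h / ((F_a + F_b) / 2)."""
    import heapq

    F = np.asarray(speed, dtype=float)
    shape = F.shape
    dist = np.full(shape, np.inf)
    heap = []
    for s in seeds:
        s = tuple(s)
        dist[s] = 0.0
        heapq.heappush(heap, (0.0, s))
    while heap:
        d, idx = heapq.heappop(heap)
        if d > dist[idx]:
            continue
        x, y, z = idx
        for ax, dd in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            nb = [x, y, z]
            nb[ax] += dd
            if not 0 <= nb[ax] < shape[ax]:
                continue
            nbt = (nb[0], nb[1], nb[2])
            c = spacing[ax] / ((F[idx] + F[nbt]) / 2.0)
            if d + c < dist[nbt]:
                dist[nbt] = d + c
                heapq.heappush(heap, (d + c, nbt))
    return dist


def brute_border(mask: np.ndarray) -> np.ndarray:
    """Border voxels by explicit 6-neighbour checks (outside = background)."""
    mask = np.asarray(mask) > 0
    out = []
    for idx in np.argwhere(mask):
        x, y, z = idx
        border = False
        for ax, d in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            q = [x, y, z]
            q[ax] += d
            if not 0 <= q[ax] < mask.shape[ax] or not mask[tuple(q)]:
                border = True
                break
        if border:
            out.append((x, y, z))
    return np.asarray(out, dtype=int).reshape(-1, 3)


def brute_surface_distances(seg, ref, spacing):
    """All-pairs pooled symmetric surface distances (ASSD, RMSSD, MSSD)."""
    sp = np.asarray(spacing, dtype=float)
    a = brute_border(seg) * sp
    b = brute_border(ref) * sp
    dm = cdist(a, b)
    pooled = np.concatenate([dm.min(axis=1), dm.min(axis=0)])
    return float(pooled.mean()), float(np.sqrt((pooled**2).mean())), float(pooled.max())


def brute_pattern(data: np.ndarray, center, window, i_min, i_max):
    """Window extraction by triple loop with replicate clamping, z slowest."""
    x, y, z = center
    wx, wy, wz = window
    rx, ry, rz = wx // 2, wy // 2, wz // 2
    nx, ny, nz = data.shape
    clamp = lambda v, n: min(max(v, 0), n - 1)
    out = []
    for k in range(-rz, rz + 1):
        for j in range(-ry, ry + 1):
            for i in range(-rx, rx + 1):
                v = data[clamp(x - i, nx), clamp(y - j, ny), clamp(z - k, nz)]
                out.append(-1.0 + 2.0 * (v - i_min) / (i_max - i_min))
    return np.asarray(out)


def loop_hidden(patterns, weights, biases):
    """Nested-loop sigmoid hidden activations."""
    n, K = len(patterns), len(biases)
    H = np.empty((n, K))
    for i in range(n):
        for k in range(K):
            u = float(np.dot(weights[k], patterns[i]) + biases[k])
            H[i, k] = 1.0 / (1.0 + np.exp(-u))
    return H
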