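"""Brute-force enumeration oracles for the texture matrices.

Deliberately naive (voxel-by-voxel loops) and independent of the package's
vectorized implementations; used only on tiny ROIs.
"""

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

DIRECTIONS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def _in(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def glcm_brute(q, mask, levels):
    counts = np.zeros((levels, levels), dtype=np.int64)
    for v in np.argwhere(mask):
        for d in OFFSETS_26:
            w = tuple(v + d)
            if _in(q.shape, w) and mask[w]:
                counts[q[tuple(v)], q[w]] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def glrlm_brute(q, mask, levels):
    runs = []
    for d in DIRECTIONS_13:
        for v in np.argwhere(mask):
            prev = tuple(v - d)
            if _in(q.shape, prev) and mask[prev] and q[prev] == q[tuple(v)]:
                continue  # not a run start
            length = 1
            cur = tuple(v + d)
            while _in(q.shape, cur) and mask[cur] and q[cur] == q[tuple(v)]:
                length += 1
                cur = tuple(np.add(cur, d))
            runs.append((q[tuple(v)], length))
    max_run = max(l for _, l in runs)
    R = np.zeros((levels, max_run), dtype=np.int64)
    for g, l in runs:
        R[g, l - 1] += 1
    return R


def glszm_brute(q, mask, levels):
    seen = np.zeros(q.shape, dtype=bool)
    zones = []
    for v in np.argwhere(mask):
        v = tuple(v)
        if seen[v]:
            continue
        g = q[v]
        stack, size = [v], 0
        seen[v] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in OFFSETS_26:
                w = tuple(np.add(cur, d))
                if _in(q.shape, w) and mask[w] and not seen[w] and q[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((g, size))
    max_zone = max(s for _, s in zones)
    Z = np.zeros((levels, max_zone), dtype=np.int64)
    for g, s in zones:
        Z[g, s - 1] += 1
    return Z


def ngtdm_brute(q, mask, levels):
    n = np.zeros(levels)
    s = np.zeros(levels)
    n_valid = 0
    for v in np.argwhere(mask):
        v = tuple(v)
        nbrs = [
            q[tuple(np.add(v, d))]
            for d in OFFSETS_26
            if _in(q.shape, tuple(np.add(v, d))) and mask[tuple(np.add(v, d))]
        ]
        if not nbrs:
            continue
        n_valid += 1
        n[q[v]] += 1
        s[q[v]] += abs(q[v] - np.mean(nbrs))
    return {"n": n, "s": s, "n_valid": n_valid}
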