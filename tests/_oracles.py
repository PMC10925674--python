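"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by a different route than the library
(within-class variance minimization instead of between-class variance
maximization; even-odd ray casting instead of shapely; exhaustive
hull-edge scan instead of shapely's rotating calipers), so agreement is
meaningful.
"""

import itertools

import numpy as np


def otsu3_oracle(hist):
    """Best (t1,t2,t3) by exhaustive minimization of within-class variance.

    Returns (total_within_class_variance, (t1, t2, t3)).  The inner loop
    over t3 is vectorized; the criterion and code path are independent of
    the library's between-class maximization.
    """
    hist = np.asarray(hist, dtype=np.float64)
    v = np.arange(256.0)
    W = np.concatenate([[0.0], np.cumsum(hist)])
    S1 = np.concatenate([[0.0], np.cumsum(hist * v)])
    S2 = np.concatenate([[0.0], np.cumsum(hist * v * v)])

    def wvar(lo, hi):
        w = W[hi] - W[lo]
        if np.ndim(w) == 0:
            if w <= 0:
                return 0.0
            s = S1[hi] - S1[lo]
            return (S2[hi] - S2[lo]) - s * s / w
        s = S1[hi] - S1[lo]
        return np.where(w > 0, (S2[hi] - S2[lo]) - s * s / np.where(w > 0, w, 1), 0.0)

    best = (np.inf, None)
    t3_all = np.arange(2, 256)
    tail = wvar(t3_all, 256)                      # class [t3, 255]
    for t1 in range(1, 254):
        w0 = wvar(0, t1)
        for t2 in range(t1 + 1, 255):
            t3 = t3_all[t3_all > t2]
            tot = (w0 + wvar(t1, t2) + wvar(t2, t3) + tail[t3 - 2])
            k = int(np.argmin(tot))
            if tot[k] < best[0] - 1e-9:
                best = (float(tot[k]), (t1, t2, int(t3[k])))
    return best


def point_in_polygon_oracle(px, py, vertices):
    """Even-odd (crossing-number) ray casting, boundary-inclusive."""
    n = len(vertices)
    # boundary check first
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12:
            if min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 and \
               min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
                return True
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def min_rect_oracle(points):
    """Minimum-area enclosing rectangle by scanning every hull-edge direction.

    Returns (area, width, height).  Relies on the theorem that the optimum
    aligns with a convex-hull edge; the hull is built by brute force
    (a point pair is a hull edge iff all points lie on one side).
    """
    pts = np.asarray(points, dtype=np.float64)
    edges = []
    for i, j in itertools.combinations(range(len(pts)), 2):
        d = pts[j] - pts[i]
        nrm = np.array([-d[1], d[0]])
        s = (pts - pts[i]) @ nrm
        if (s >= -1e-9).all() or (s <= 1e-9).all():
            edges.append(d / np.linalg.norm(d))
    best = (np.inf, None, None)
    for u in edges:
        v = np.array([-u[1], u[0]])
        a = pts @ u
        b = pts @ v
        w, h = a.max() - a.min(), b.max() - b.min()
        if w * h < best[0]:
            best = (w * h, w, h)
    return best


def optimal_matching_oracle(auto, truth, radius):
    """Maximum-cardinality one-to-one matching by exhaustive enumeration."""
    na, nt = len(auto), len(truth)
    D = np.array([[np.hypot(a[0] - t[0], a[1] - t[1]) for t in truth]
                  for a in auto])
    best = 0
    for k in range(min(na, nt), 0, -1):
        for subset_a in itertools.permutations(range(na), k):
            for subset_t in itertools.combinations(range(nt), k):
                if all(D[i, j] <= radius
                       for i, j in zip(subset_a, subset_t)):
                    return k
    return best
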