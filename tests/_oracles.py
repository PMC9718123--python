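"""Independent brute-force oracles used only by the tests.

Each oracle is deliberately written with the most naive correct algorithm
available (explicit loops, exhaustive enumeration, hand-expanded sums of
squares) so that it shares no code path with the package implementation it
checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """All connected components of a 2-D boolean grid via BFS flood fill."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if not binary[r, c] or seen[r, c]:
                continue
            comp = set()
            q = deque([(r, c)])
            seen[r, c] = True
            while q:
                cr, cc = q.popleft()
                comp.add((cr, cc))
                for dr, dc in nbrs:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        q.append((nr, nc))
            comps.append(comp)
    return comps


def convex_contains(vertices, point, tol=1e-12) -> bool:
    """Point in convex polygon (inside or on boundary) by edge cross products."""
    n = len(vertices)
    # orientation of the polygon
    signs = []
    px, py = point
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        signs.append(cross)
    pos = any(s > tol for s in signs)
    neg = any(s < -tol for s in signs)
    return not (pos and neg)


def pair_count_auc(case_values, control_values) -> float:
    """(concordant + half ties) / (n_case * n_control) by explicit double loop."""
    wins = 0.0
    for x in case_values:
        for y in control_values:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(case_values) * len(control_values))


def midrank(values) -> list[float]:
    """Average ranks for ties, computed by explicit enumeration."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def spearman_oracle(x, y) -> float:
    """Midrank-then-Pearson Spearman correlation."""
    return pearson(midrank(x), midrank(y))


def icc_oracle(table: np.ndarray, model: str) -> float:
    """ICC(2,1) / ICC(3,1) by hand-expanded sums of squares, explicit loops."""
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(table[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "two_way_random_absolute_single":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if model == "two_way_mixed_consistency_single":
        return (msr - mse) / (msr + (k - 1) * mse)
    raise ValueError(model)


def otsu_oracle(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu split by brute force over every interior bin edge."""
    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    mids = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    variances = []
    for split in range(1, n_bins):
        w0 = counts[:split].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            variances.append(-np.inf)
            continue
        mu0 = (counts[:split] * mids[:split]).sum() / counts[:split].sum()
        mu1 = (counts[split:] * mids[split:]).sum() / counts[split:].sum()
        variances.append(w0 * w1 * (mu0 - mu1) ** 2)
    peak = max(variances)
    # lowest split within float noise of the plateau maximum
    for split, var in enumerate(variances, start=1):
        if var >= peak - 1e-9 * abs(peak):
            return float(edges[split])
    raise AssertionError("unreachable")


def ellipsoid_count_oracle(shape, spacing, center, semi_axes) -> int:
    """Voxel-center ellipsoid membership count by explicit triple loop."""
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                x = (i * spacing[0] - center[0]) / semi_axes[0]
                y = (j * spacing[1] - center[1]) / semi_axes[1]
                z = (k * spacing[2] - center[2]) / semi_axes[2]
                if x * x + y * y + z * z <= 1.0:
                    count += 1
    return count
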