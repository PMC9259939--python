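"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: distances are
computed by exhaustive loops, rank-sum p-values by direct enumeration over
index combinations, and distribution moments by independent scipy samplers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def expand_masks_oracle(labels: np.ndarray, expansion_factor: float,
                        cap_margin: float = 3.0) -> np.ndarray:
    """Exhaustive per-pixel nearest-nucleus area-budget assignment.

    Definition: every background pixel within the per-label growth cap is a
    candidate claim (squared Euclidean distance to the nearest pixel of that
    nucleus, computed here by brute force over all nucleus pixels). Claims
    are processed in increasing (d^2, label, row, col) order; a claim
    succeeds if the pixel is unassigned and the label's area is still below
    ``expansion_factor`` times its nucleus area.
    """
    labels = np.asarray(labels)
    out = labels.astype(np.int64).copy()
    ids = sorted(int(k) for k in np.unique(labels) if k > 0)
    if not ids:
        return out
    nuc_pixels = {k: np.argwhere(labels == k) for k in ids}
    area = {k: len(nuc_pixels[k]) for k in ids}
    budget = {k: expansion_factor * area[k] for k in ids}

    claims = []
    bg = np.argwhere(labels == 0)
    for k in ids:
        pix = nuc_pixels[k]
        r_eq = math.sqrt(area[k] / math.pi)
        cap = math.sqrt(expansion_factor) * r_eq + cap_margin
        cap2 = int(cap * cap)  # mirror of the implementation's integer cut
        for (r, c) in bg:
            d2 = int(((pix[:, 0] - r) ** 2 + (pix[:, 1] - c) ** 2).min())
            if d2 <= cap2:
                claims.append((d2, k, int(r), int(c)))
    claims.sort()
    for d2, k, r, c in claims:
        if area[k] >= budget[k] or out[r, c] != 0:
            continue
        out[r, c] = k
        area[k] += 1
    return out


def rank_sum_p_bruteforce(x, y) -> float:
    """Two-sided exact rank-sum p by direct enumeration (tie-free or midranks).

    Independent of the package: ranks come from a hand-rolled midrank
    routine, and the null distribution is enumerated over index combinations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n1 = x.size
    w_obs = ranks[:n1].sum()
    n_le = n_ge = total = 0
    for comb in itertools.combinations(range(pooled.size), n1):
        w = sum(ranks[i] for i in comb)
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def nb_moments_oracle(mean: float, dispersion: float, n: int, seed: int):
    """Monte-Carlo mean/variance of NB(mean, dispersion) via scipy's sampler."""
    from scipy import stats as sps

    p = dispersion / (dispersion + mean)
    draws = sps.nbinom(dispersion, p).rvs(size=n, random_state=np.random.RandomState(seed))
    return float(draws.mean()), float(draws.var(ddof=1))


def match_cells_to_truth(df, gt, max_dist_px: float = 5.0):
    """Nearest-centroid matching of quantified cells to ground-truth cells.

    Returns a list of (row, GroundTruthCell) pairs for matched, non-edge cells.
    """
    import numpy as np

    gtc = np.array([c.centroid_px for c in gt.cells])
    pairs = []
    for _, row in df.iterrows():
        if row.get("edge_cell", False):
            continue
        d = np.hypot(gtc[:, 0] - row["centroid_row"], gtc[:, 1] - row["centroid_col"])
        j = int(d.argmin())
        if d[j] <= max_dist_px:
            pairs.append((row, gt.cells[j]))
    return pairs
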