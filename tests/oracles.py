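"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by direct enumeration or per-voxel
looping, deliberately sharing no code with the implementation it checks.
"""

import itertools
import math

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's probability.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):  # tolerate float ties
            total += px
    return total


def mann_whitney_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p by exhaustive relabeling (small n)."""
    pooled = list(a) + list(b)
    na, n = len(a), len(pooled)

    def u_stat(ga, gb):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in ga for y in gb
        )

    u_obs = u_stat(a, b)
    us = []
    for comb in itertools.combinations(range(n), na):
        sel = set(comb)
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n) if i not in sel]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    eps = 1e-9
    p = 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean())
    return min(1.0, p)


def scar_score_lookup(pct: float) -> float:
    """Bin lookup: 0 iff 0; (0,25]->1; (25,50]->2; (50,75]->3; (75,100]->4."""
    if np.isnan(pct):
        return float("nan")
    if pct <= 0:
        return 0.0
    if pct <= 25:
        return 1.0
    if pct <= 50:
        return 2.0
    if pct <= 75:
        return 3.0
    return 4.0


def transmural_count(scores) -> int:
    return sum(1 for s in scores if not np.isnan(s) and s >= 3)


def territory_mean(scores, segment_ids) -> float:
    vals = [scores[i - 1] for i in segment_ids if not np.isnan(scores[i - 1])]
    return float(np.mean(vals)) if vals else float("nan")


def phantom_voxel_labels(spec):
    """Re-derive every voxel's tissue label from its polar coordinates.

    Pure per-voxel loop over the phantom's documented geometric rules:
    returns (myocardium, core, border) boolean volumes.
    """
    n = spec.grid_size
    cx, cy = spec.center_mm()
    endo = spec.endo_radii()
    epi = spec.epi_radii()
    start, stop = spec.scar_slice_range
    half = spec.scar_angular_extent_deg / 2.0
    full_ring = spec.scar_angular_extent_deg >= 360.0
    myo = np.zeros((spec.n_slices, n, n), dtype=bool)
    core = np.zeros_like(myo)
    border = np.zeros_like(myo)
    for s in range(spec.n_slices):
        wall = epi[s] - endo[s]
        r_scar = endo[s] + spec.scar_transmurality * wall
        r_core = endo[s] + (1 - spec.border_rim_fraction) * spec.scar_transmurality * wall
        scar_slice = (
            start <= s < stop
            and spec.scar_angular_extent_deg > 0
            and spec.scar_transmurality > 0
        )
        for row in range(n):
            for col in range(n):
                x = col * spec.pixel_spacing_mm - cx
                y = row * spec.pixel_spacing_mm - cy
                r = math.hypot(x, y)
                if not (endo[s] <= r < epi[s]):
                    continue
                myo[s, row, col] = True
                if not scar_slice:
                    continue
                d = math.degrees(math.atan2(y, x)) - spec.scar_angular_center_deg
                d = -((-d + 180.0) % 360.0 - 180.0)  # wrap to (-180, 180]
                in_wedge = full_ring or (-half <= d < half)
                if in_wedge and r < r_scar:
                    if r < r_core:
                        core[s, row, col] = True
                    else:
                        border[s, row, col] = True
    return myo, core, border


def segment_of_voxel(x, y, cx, cy, rv_x, rv_y, tier):
    """Per-voxel AHA segment from the documented tier/angle convention."""
    basal = (1, 6, 5, 4, 3, 2)
    mid = (7, 12, 11, 10, 9, 8)
    apical = (13, 16, 15, 14)
    phi = math.degrees(math.atan2(y - cy, x - cx))
    phi_rv = math.degrees(math.atan2(rv_y - cy, rv_x - cx))
    delta = (phi - phi_rv) % 360.0
    if tier == "apex":
        return 17
    if tier == "basal":
        return basal[int(delta // 60) % 6]
    if tier == "mid":
        return mid[int(delta // 60) % 6]
    return apical[int(delta // 90) % 4]
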