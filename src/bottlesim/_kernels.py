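"""Numba kernels for the O(N²) inner loops of the stepper.

These are direct transcriptions of the model rules; the pytest suite checks
them against independent numpy re-implementations.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def headway_spacing_kernel(
    pos: np.ndarray, e: np.ndarray, l: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal spacing s_i over the headway set and the argmin index.

    j is in i's headway when it lies in the forward half-plane of e_i and
    its centre is within lateral distance l of i's movement line. Ties take
    the lowest index; empty sets give (inf, −1).
    """
    n = pos.shape[0]
    s = np.full(n, np.inf)
    jmin = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        ex = e[i, 0]
        ey = e[i, 1]
        best = np.inf
        bj = -1
        for j in range(n):
            if j == i:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if ex * dx + ey * dy < 0.0:
                continue
            if abs(ex * dy - ey * dx) >= l:
                continue
            d = (dx * dx + dy * dy) ** 0.5
            if d < best:
                best = d
                bj = j
        s[i] = best
        jmin[i] = bj
    return s, jmin


@nb.njit(cache=True)
def contact_gamma_kernel(
    pos: np.ndarray, disp: np.ndarray, gamma: np.ndarray, l_contact: float
) -> np.ndarray:
    """Largest step fractions that keep all pairwise distances ≥ l_contact.

    Agents are resolved in ascending index order: agent i moves along its
    displacement until first contact with either the finalised position of
    an already-resolved agent or the held position of a not-yet-resolved
    one. ``gamma`` carries pre-imposed caps (e.g. 0 for wall-frozen agents)
    and is updated in place.
    """
    n = pos.shape[0]
    l_sq = l_contact * l_contact
    cur = pos.copy()
    for i in range(n):
        if gamma[i] <= 0.0:
            continue
        dx = disp[i, 0]
        dy = disp[i, 1]
        a = dx * dx + dy * dy
        if a <= 0.0:
            continue
        step = a**0.5
        screen = step * step + 2.0 * l_contact * step
        g = gamma[i]
        for j in range(n):
            if j == i:
                continue
            pqx = pos[i, 0] - cur[j, 0]
            pqy = pos[i, 1] - cur[j, 1]
            cc = pqx * pqx + pqy * pqy - l_sq
            if cc > screen:  # cannot reach contact within this step
                continue
            bq = 2.0 * (dx * pqx + dy * pqy)
            if bq >= 0.0:  # receding
                continue
            disc = bq * bq - 4.0 * a * cc
            if disc <= 0.0:
                continue
            g_hit = (-bq - disc**0.5) / (2.0 * a)
            if g_hit < g:
                g = g_hit
        if g < 0.0:
            g = 0.0
        gamma[i] = g
        cur[i, 0] = pos[i, 0] + g * dx
        cur[i, 1] = pos[i, 1] + g * dy
    return gamma
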