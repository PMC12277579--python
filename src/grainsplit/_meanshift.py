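"""Numba kernel for joint spatial/color mean-shift filtering.

Each pixel starts a mean-shift trajectory in the joint (row, col, c1, c2, c3)
domain with a flat kernel: a square spatial window of half-width ``sr`` and a
Euclidean color ball of radius ``cr``.  The trajectory stops when the color
shift drops below 0.5 intensity units or after ``max_iter`` steps; the pixel
takes the final window mean color.  On flat regions (paper background) a
single iteration converges, so the average cost is close to one window pass
per pixel.
"""

import numpy as np
from numba import njit, prange


@njit(cache=True, fastmath=True, parallel=True)
def meanshift_filter(img, sr, cr2, max_iter):
    h, w, _ = img.shape
    out = np.empty_like(img)
    for i in prange(h):
        for j in range(w):
            cy = float(i)
            cx = float(j)
            c0 = img[i, j, 0]
            c1 = img[i, j, 1]
            c2 = img[i, j, 2]
            for _ in range(max_iter):
                r0 = int(cy + 0.5) - sr
                r1 = int(cy + 0.5) + sr
                q0 = int(cx + 0.5) - sr
                q1 = int(cx + 0.5) + sr
                if r0 < 0:
                    r0 = 0
                if q0 < 0:
                    q0 = 0
                if r1 > h - 1:
                    r1 = h - 1
                if q1 > w - 1:
                    q1 = w - 1
                sy = 0.0
                sx = 0.0
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                n = 0
                for y in range(r0, r1 + 1):
                    for x in range(q0, q1 + 1):
                        d0 = img[y, x, 0] - c0
                        d1 = img[y, x, 1] - c1
                        d2 = img[y, x, 2] - c2
                        if d0 * d0 + d1 * d1 + d2 * d2 <= cr2:
                            sy += y
                            sx += x
                            s0 += img[y, x, 0]
                            s1 += img[y, x, 1]
                            s2 += img[y, x, 2]
                            n += 1
                if n == 0:
                    break
                ny = sy / n
                nx = sx / n
                n0 = s0 / n
                n1 = s1 / n
                n2 = s2 / n
                shift = (n0 - c0) ** 2 + (n1 - c1) ** 2 + (n2 - c2) ** 2
                cy = ny
                cx = nx
                c0 = n0
                c1 = n1
                c2 = n2
                if shift < 0.25:
                    break
            out[i, j, 0] = c0
            out[i, j, 1] = c1
            out[i, j, 2] = c2
    return out
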