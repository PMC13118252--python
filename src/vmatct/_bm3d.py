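"""Numba kernel for slice-wise block-matching and 3D filtering.

Hard-thresholding BM3D on a 2D slice: square reference blocks on a step
grid are matched against candidates in a local search window by mean
squared difference (raster-order tie-break), the best matches are stacked,
the stack is sparsified by an orthonormal separable 3D transform (2D DCT
per block, 1D DCT along the stack), hard-thresholded at
``multiplier * sigma`` (the group DC coefficient is exempt so constant
regions are preserved exactly), inverse transformed, and aggregated with
per-group weights 1 / n_retained.
"""

import numpy as np
from numba import njit
from scipy.fft import dct

__all__ = ["bm3d_slice", "dct_matrix", "dct_stack_matrices"]


def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal DCT-II matrix D with (D @ x) = dct(x, norm='ortho')."""
    return np.ascontiguousarray(dct(np.eye(n), axis=0, norm="ortho"))


def dct_stack_matrices(max_group: int) -> np.ndarray:
    """Padded array of DCT matrices for stack lengths 1..max_group."""
    out = np.zeros((max_group + 1, max_group, max_group))
    for m in range(1, max_group + 1):
        out[m, :m, :m] = dct_matrix(m)
    return np.ascontiguousarray(out)


@njit(cache=True, fastmath=True)
def bm3d_slice(img, sigma, bs, radius, maxg, mult, step, D2, D1):
    """Denoise one 2D slice; returns a new array of the same shape."""
    nx, ny = img.shape
    num = np.zeros((nx, ny))
    den = np.zeros((nx, ny))
    thr = mult * sigma
    D2T = np.ascontiguousarray(D2.T)

    # reference block positions: step grid plus the final flush position
    n_rx = (nx - bs) // step + 1
    if (n_rx - 1) * step != nx - bs:
        n_rx += 1
    n_ry = (ny - bs) // step + 1
    if (n_ry - 1) * step != ny - bs:
        n_ry += 1

    best_d = np.empty(maxg)
    best_x = np.empty(maxg, dtype=np.int64)
    best_y = np.empty(maxg, dtype=np.int64)
    coef = np.empty((maxg, bs, bs))
    stack = np.empty((maxg, bs, bs))

    for irx in range(n_rx):
        rx = irx * step
        if rx > nx - bs:
            rx = nx - bs
        for iry in range(n_ry):
            ry = iry * step
            if ry > ny - bs:
                ry = ny - bs
            # --- block matching ---
            x0 = rx - radius
            if x0 < 0:
                x0 = 0
            x1 = rx + radius
            if x1 > nx - bs:
                x1 = nx - bs
            y0 = ry - radius
            if y0 < 0:
                y0 = 0
            y1 = ry + radius
            if y1 > ny - bs:
                y1 = ny - bs
            m = 0
            for cx in range(x0, x1 + 1):
                for cy in range(y0, y1 + 1):
                    d = 0.0
                    for a in range(bs):
                        for b in range(bs):
                            diff = img[cx + a, cy + b] - img[rx + a, ry + b]
                            d += diff * diff
                    d /= bs * bs
                    # insertion sort, strict < keeps raster order on ties
                    if m < maxg:
                        pos = m
                        while pos > 0 and d < best_d[pos - 1]:
                            best_d[pos] = best_d[pos - 1]
                            best_x[pos] = best_x[pos - 1]
                            best_y[pos] = best_y[pos - 1]
                            pos -= 1
                        best_d[pos] = d
                        best_x[pos] = cx
                        best_y[pos] = cy
                        m += 1
                    elif d < best_d[maxg - 1]:
                        pos = maxg - 1
                        while pos > 0 and d < best_d[pos - 1]:
                            best_d[pos] = best_d[pos - 1]
                            best_x[pos] = best_x[pos - 1]
                            best_y[pos] = best_y[pos - 1]
                            pos -= 1
                        best_d[pos] = d
                        best_x[pos] = cx
                        best_y[pos] = cy
            # --- 2D transform of each matched block ---
            for g in range(m):
                bx = best_x[g]
                by = best_y[g]
                stack[g, :, :] = np.dot(
                    D2, np.dot(img[bx:bx + bs, by:by + bs].copy(), D2T))
            # --- 1D transform along the stack ---
            Dm = D1[m]
            for a in range(bs):
                for b in range(bs):
                    for i in range(m):
                        s = 0.0
                        for j in range(m):
                            s += Dm[i, j] * stack[j, a, b]
                        coef[i, a, b] = s
            # --- hard threshold (group DC exempt) ---
            nret = 0
            for i in range(m):
                for a in range(bs):
                    for b in range(bs):
                        if i == 0 and a == 0 and b == 0:
                            nret += 1
                            continue
                        if abs(coef[i, a, b]) <= thr:
                            coef[i, a, b] = 0.0
                        else:
                            nret += 1
            w = 1.0 / nret
            # --- inverse transforms ---
            for a in range(bs):
                for b in range(bs):
                    for j in range(m):
                        s = 0.0
                        for i in range(m):
                            s += Dm[i, j] * coef[i, a, b]
                        stack[j, a, b] = s
            for g in range(m):
                rec = np.dot(D2T, np.dot(stack[g, :, :].copy(), D2))
                bx = best_x[g]
                by = best_y[g]
                for a in range(bs):
                    for b in range(bs):
                        num[bx + a, by + b] += w * rec[a, b]
                        den[bx + a, by + b] += w
    out = np.empty((nx, ny))
    for a in range(nx):
        for b in range(ny):
            if den[a, b] > 0.0:
                out[a, b] = num[a, b] / den[a, b]
            else:
                out[a, b] = img[a, b]
    return out
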