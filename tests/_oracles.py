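"""Independent brute-force oracles used by the tests.

Everything here is written as plainly as possible (explicit loops, no
shared code with the package beyond numpy) so that agreement with the
package is evidence, not tautology.
"""

import math

import numpy as np


def sobel_magnitude_loops(img: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude with edge replication, by loops.

    Matches scipy.ndimage.sobel's axis convention: axis-0 derivative uses
    the smoothing kernel along axis 1 and vice versa.
    """
    rows, cols = img.shape
    padded = np.pad(img, 1, mode="edge")
    d0 = np.zeros_like(img, dtype=float)
    d1 = np.zeros_like(img, dtype=float)
    deriv = (-1.0, 0.0, 1.0)
    smooth = (1.0, 2.0, 1.0)
    for r in range(rows):
        for c in range(cols):
            a0 = 0.0
            a1 = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    v = padded[r + 1 + dr, c + 1 + dc]
                    a0 += deriv[dr + 1] * smooth[dc + 1] * v
                    a1 += smooth[dr + 1] * deriv[dc + 1] * v
            d0[r, c] = a0
            d1[r, c] = a1
    return np.sqrt(d0**2 + d1**2)


def quantise_loops(values: np.ndarray, levels: int) -> np.ndarray:
    top = values.max()
    out = np.zeros(values.shape, dtype=int)
    if top <= 0:
        return out
    for idx in np.ndindex(values.shape):
        q = int(round(values[idx] * (levels - 1) / top))
        out[idx] = min(max(q, 0), levels - 1)
    return out


def glgcm_oracle(img: np.ndarray, gray_levels: int = 16, grad_levels: int = 16):
    """15 GLGCM statistics of a fully masked image, from the explicit
    per-pixel (gray, grad) joint table."""
    grad = sobel_magnitude_loops(np.asarray(img, dtype=float))
    qg = quantise_loops(np.asarray(img, dtype=float), gray_levels)
    qs = quantise_loops(grad, grad_levels)
    table = np.zeros((gray_levels, grad_levels))
    for idx in np.ndindex(img.shape):
        table[qg[idx], qs[idx]] += 1.0
    p = table / table.sum()

    p_i = [sum(p[i][j] for j in range(grad_levels)) for i in range(gray_levels)]
    p_j = [sum(p[i][j] for i in range(gray_levels)) for j in range(grad_levels)]
    mu_i = sum(i * p_i[i] for i in range(gray_levels))
    mu_j = sum(j * p_j[j] for j in range(grad_levels))
    var_i = sum((i - mu_i) ** 2 * p_i[i] for i in range(gray_levels))
    var_j = sum((j - mu_j) ** 2 * p_j[j] for j in range(grad_levels))
    sd_i, sd_j = math.sqrt(var_i), math.sqrt(var_j)

    small_grads = sum(
        p[i][j] / (j + 1) ** 2
        for i in range(gray_levels) for j in range(grad_levels)
    )
    big_grads = sum(
        p[i][j] * j**2 for i in range(gray_levels) for j in range(grad_levels)
    )
    gray_asym = sum(v**2 for v in p_i)
    grads_asym = sum(v**2 for v in p_j)
    energy = sum(
        p[i][j] ** 2 for i in range(gray_levels) for j in range(grad_levels)
    )
    if sd_i > 0 and sd_j > 0:
        corr = sum(
            (i - mu_i) * (j - mu_j) * p[i][j]
            for i in range(gray_levels) for j in range(grad_levels)
        ) / (sd_i * sd_j)
    else:
        corr = 0.0
    ent = lambda q: -sum(v * math.log(v) for v in np.ravel(q) if v > 0)
    inertia = sum(
        (i - j) ** 2 * p[i][j]
        for i in range(gray_levels) for j in range(grad_levels)
    )
    homog = sum(
        p[i][j] / (1 + (i - j) ** 2)
        for i in range(gray_levels) for j in range(grad_levels)
    )
    return np.array([
        small_grads, big_grads, gray_asym, grads_asym, energy,
        mu_i, mu_j, var_i, var_j, corr,
        ent(p_i), ent(p_j), ent(p), inertia, homog,
    ])


def ols_predict(X: np.ndarray, y: np.ndarray, Xq: np.ndarray) -> np.ndarray:
    """Ordinary least squares with intercept via lstsq."""
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.hstack([np.ones((Xq.shape[0], 1)), Xq]) @ beta
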