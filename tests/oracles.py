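"""Independent oracles used by the test suite.

These are deliberately separate implementations (brute force, closed form,
permutation, hand-coded NIPALS) of quantities the package computes by other
routes; they must stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np


def permutation_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = 100_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the correlation of x and y.

    Permutes y, using |r| as the statistic (equivalent to the |slope t| under
    permutation).  Includes the identity permutation in the numerator and
    denominator (add-one rule).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = pc @ xc / (np.linalg.norm(xc) * np.linalg.norm(pc, axis=1))
    yc = y - y.mean()
    r_obs = (yc @ xc) / (np.linalg.norm(xc) * np.linalg.norm(yc))
    return (1 + np.sum(np.abs(r_perm) >= np.abs(r_obs))) / (1 + n_perm)


def nipals_pls1_vip(X: np.ndarray, y: np.ndarray, ncomp: int) -> np.ndarray:
    """VIP scores from a hand-coded PLS1 NIPALS fit.

    X must already be autoscaled and y centered.  Classic PLS1: for each
    component, w = X'y / ||X'y||, t = Xw, p = X't/(t't), q = y't/(t't), then
    deflate X and y.  VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a)
    with SSY_a = q_a^2 t_a't_a (weights are unit-norm already).
    """
    X = np.array(X, dtype=float, copy=True)
    y = np.array(y, dtype=float, copy=True)
    p_feat = X.shape[1]
    Ws, ssy = [], []
    for _ in range(ncomp):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = t @ t
        p_load = X.T @ t / tt
        q = (y @ t) / tt
        X = X - np.outer(t, p_load)
        y = y - q * t
        Ws.append(w)
        ssy.append(q**2 * tt)
    W = np.column_stack(Ws)
    ssy = np.asarray(ssy)
    return np.sqrt(p_feat * (W**2 * ssy).sum(axis=1) / ssy.sum())


def masked_mean_max(arr: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Brute-force mean and max of arr over a boolean mask (loop-free oracle)."""
    vals = [arr[r, c] for r, c in zip(*np.nonzero(mask))]
    return float(np.mean(vals)), float(np.max(vals))


def gaussian_kernel_center(sigma: float, truncate: float = 4.0) -> float:
    """Center weight of the discrete 2-D Gaussian blur kernel.

    Matches scipy.ndimage.gaussian_filter's truncated, normalized separable
    kernel; the blurred image of an isolated delta of amplitude A peaks at
    A * g0**2 where g0 is this 1-D center weight.
    """
    radius = int(truncate * sigma + 0.5)
    i = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (i / sigma) ** 2)
    g = g / g.sum()
    return float(g[radius])


def welch_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook Welch two-sample t statistic and two-sided p-value."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(2 * tdist.sf(abs(t), df))
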