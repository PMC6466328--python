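"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(explicit loops, explicit refits, explicit set arithmetic) and stays
independent of the implementation path it checks.
"""

from __future__ import annotations

import numpy as np


def psar10g_bruteforce(
    sar: np.ndarray,
    labels: np.ndarray,
    voxel_size: float,
    rho_by_label: np.ndarray,
    target_mass: float,
) -> tuple[float, tuple[int, int, int]]:
    """Exhaustive cube-growing peak spatial SAR.

    For every tissue voxel, extract every centred cube explicitly and apply
    the fractional outer-shell rule; cubes that exit the grid before
    reaching the target mass invalidate the voxel.  Ties keep the first
    (C-order) voxel.
    """
    shape = labels.shape
    mass = rho_by_label[labels] * voxel_size**3
    power = sar * mass
    best = None
    best_loc = None
    for i in range(shape[0]):
        for j in range(shape[1]):
            for l in range(shape[2]):
                if labels[i, j, l] == 0:
                    continue
                m_prev = 0.0
                p_prev = 0.0
                value = None
                for k in range((min(shape) + 1) // 2 + 1):
                    if (
                        i - k < 0
                        or j - k < 0
                        or l - k < 0
                        or i + k >= shape[0]
                        or j + k >= shape[1]
                        or l + k >= shape[2]
                    ):
                        break  # cube exits the grid: voxel invalid
                    cube = (
                        slice(i - k, i + k + 1),
                        slice(j - k, j + k + 1),
                        slice(l - k, l + k + 1),
                    )
                    m = float(mass[cube].sum())
                    p = float(power[cube].sum())
                    if m >= target_mass:
                        frac = (target_mass - m_prev) / (m - m_prev)
                        value = (p_prev + frac * (p - p_prev)) / target_mass
                        break
                    m_prev, p_prev = m, p
                if value is not None and (best is None or value > best):
                    best = value
                    best_loc = (i, j, l)
    return best, best_loc


def loo_refit(phi: np.ndarray, y: np.ndarray) -> float:
    """Literal leave-one-out error: refit N times, one point held out."""
    n = len(y)
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        coef, *_ = np.linalg.lstsq(phi[keep], y[keep], rcond=None)
        errs[i] = (y[i] - phi[i] @ coef) ** 2
    return float(errs.mean())


def mass_weighted_mean(values: np.ndarray, masses: np.ndarray) -> float:
    """Direct summation weighted mean."""
    num = 0.0
    den = 0.0
    for v, m in zip(values, masses):
        num += v * m
        den += m
    return num / den


def random_label_phantom(rng: np.random.Generator, shape, n_tissues: int = 3):
    """Random labelled grid plus per-label conductivity/density lookups.

    Label 0 is background; labels 1..n_tissues have random properties.
    """
    labels = rng.integers(0, n_tissues + 1, size=shape).astype(np.int16)
    sigma = np.concatenate([[0.0], rng.uniform(0.1, 1.5, n_tissues)])
    rho = np.concatenate([[0.0], rng.uniform(500.0, 2000.0, n_tissues)])
    return labels, sigma, rho
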