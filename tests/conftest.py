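"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from echomatch import PhantomSpec, generate_reference


# --- phantom fixtures -------------------------------------------------------

TINY = dict(
    grid_shape=(48, 48, 48),
    prostate_semi_axes_mm=(7.0, 6.0, 6.5),
    n_landmarks=3,
)
MICRO = dict(
    grid_shape=(32, 32, 32),
    prostate_semi_axes_mm=(3.5, 3.2, 3.4),
    n_landmarks=1,
)
SMALL64 = dict(
    grid_shape=(64, 64, 64),
    prostate_semi_axes_mm=(12.0, 10.0, 11.0),
    n_landmarks=3,
)


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(**TINY, seed=7)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec):
    return generate_reference(tiny_spec)


@pytest.fixture(scope="session")
def bundle64():
    return generate_reference(PhantomSpec(**SMALL64, seed=11))


# --- independent oracles ----------------------------------------------------


def brute_weighted_ncc(t_vals, weights, guide, base, d):
    """Direct weighted NCC at one integer displacement (loop-free reference)."""
    p = np.asarray(base) + np.asarray(d)
    tshape = np.asarray(t_vals.shape)
    if np.any(p < 0) or np.any(p + tshape > np.asarray(guide.shape)):
        return None
    patch = guide[tuple(slice(a, a + n) for a, n in zip(p, tshape))]
    w = weights
    wsum = w.sum()
    tm = (w * t_vals).sum() / wsum
    gm = (w * patch).sum() / wsum
    tc, gc = t_vals - tm, patch - gm
    tv = (w * tc * tc).sum()
    gv = (w * gc * gc).sum()
    if gv <= 0 or tv <= 0:
        return None
    return (w * tc * gc).sum() / np.sqrt(tv * gv)


def brute_argmax_ncc(t_vals, weights, guide, base, lo, hi):
    """Exhaustive weighted-NCC argmax over an inclusive displacement box."""
    best_d, best_s = None, -np.inf
    for d in itertools.product(
        *[range(int(a), int(b) + 1) for a, b in zip(lo, hi)]
    ):
        s = brute_weighted_ncc(t_vals, weights, guide, base, d)
        if s is None:
            continue
        better = s > best_s
        if s == best_s and best_d is not None:
            # match the production tie-break: smaller norm, then lexicographic
            better = (np.dot(d, d), d) < (np.dot(best_d, best_d), tuple(best_d))
        if better:
            best_d, best_s = np.asarray(d), s
    return best_d, best_s


def enum_mann_whitney(x, y):
    """Exact two-sided Mann-Whitney p by full label enumeration (tie-free)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = sum(xi > yj for xi in x for yj in y)
    center = len(x) * len(y) / 2.0
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(a > b for a in xs for b in ys))
    us = np.asarray(us, float)
    p = np.mean(np.abs(us - center) >= abs(obs - center) - 1e-12)
    return obs, min(1.0, float(p))


def enum_ansari(x, y):
    """Exact two-sided Ansari-Bradley p by full label enumeration (tie-free)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    ranks = np.arange(1, total + 1)
    scores_sorted = np.minimum(ranks, total + 1 - ranks)
    sc = np.empty(total)
    sc[np.argsort(pooled)] = scores_sorted
    obs = sc[:n].sum()
    vals = np.array(
        [
            sc[list(comb)].sum()
            for comb in itertools.combinations(range(total), n)
        ]
    )
    lo = np.mean(vals <= obs + 1e-12)
    hi = np.mean(vals >= obs - 1e-12)
    return obs, min(1.0, float(2 * min(lo, hi)))
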