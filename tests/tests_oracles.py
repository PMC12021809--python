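"""Independent brute-force oracles and synthetic cohorts shared by the
unit and acceptance tests.  Deliberately naive implementations: double loops
and direct formula evaluation, kept free of the package's optimized paths."""

import math

import numpy as np

from fibrotwin.classifier import (ClassifierCase, FusionConfig, TrainConfig,
                                  train_classifier)

STACK_SHAPE = (5, 16, 16)


def brute_force_entropy(values: np.ndarray) -> float:
    """Literal double-loop mass-weighted entropy (the printed formula)."""
    total = values.sum()
    acc = 0.0
    ny, nx = values.shape
    for i in range(ny):
        for j in range(nx):
            p = values[i, j] / total
            if p > 0:
                acc -= p * math.log2(p)
    return acc / math.log2(ny * nx)


def brute_force_morans(values: np.ndarray) -> float:
    """O(n^2) Moran's I with row-normalized rook weights."""
    ny, nx = values.shape
    z = values - values.mean()
    num = 0.0
    for i in range(ny):
        for j in range(nx):
            nbrs = [(i + di, j + dj)
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                    if 0 <= i + di < ny and 0 <= j + dj < nx]
            w = 1.0 / len(nbrs)
            for a, b in nbrs:
                num += w * z[i, j] * z[a, b]
    return num / (z * z).sum()


def brute_force_winding(phase: np.ndarray) -> list:
    """Plaquette-loop phase integral for every 2x2 plaquette."""
    out = []
    ny, nx = phase.shape
    for r in range(ny - 1):
        for c in range(nx - 1):
            loop = [phase[r, c], phase[r, c + 1], phase[r + 1, c + 1],
                    phase[r + 1, c], phase[r, c]]
            tot = 0.0
            for a, b in zip(loop[:-1], loop[1:]):
                d = b - a
                tot += (d + math.pi) % (2 * math.pi) - math.pi
            q = int(round(tot / (2 * math.pi)))
            if q != 0:
                out.append((r, c, q))
    return out


def separable_cohort(n, seed, shuffle_labels=False):
    """Cases whose four labels are threshold functions of the stack
    intensity: linearly separable by construction."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        s = rng.uniform(0, 1)
        la = np.clip(s + 0.05 * rng.standard_normal(STACK_SHAPE), 0, 1)
        ra = np.clip(s + 0.05 * rng.standard_normal(STACK_SHAPE), 0, 1)
        labels = np.array([float(s > thr) for thr in (0.35, 0.45, 0.55, 0.65)])
        cases.append(ClassifierCase(la, ra, labels, f"case{i}",
                                    f"la{i % 10}", f"ra{i % 10}"))
    if shuffle_labels:
        perm = np.random.default_rng(seed + 1).permutation(n)
        shuffled = [cases[p].labels for p in perm]
        for c, lab in zip(cases, shuffled):
            c.labels = lab
    return cases


def train_fast(train, val, mode="concat"):
    cfg = TrainConfig(learning_rate=1e-3, epochs=50, batch_size=16,
                      patience=50, seed=0, backbone_width=4)
    model, _ = train_classifier(train, FusionConfig(mode=mode), cfg,
                                validation_cases=val)
    return model
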