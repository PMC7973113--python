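"""Shared fixtures and independent oracles used across the suite.

The oracles here are deliberately written as plain loops over Python floats,
independent of the package's vectorized code paths, so they can arbitrate.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from sapnn import (
    ClassLabel,
    GeneratorConfig,
    SpectralDataset,
    generate,
    make_uniform_grid,
)


# ---------------------------------------------------------------- oracles


def sd_brute_force(y_bins, z_labels) -> float:
    """Statistical dependency by explicit contingency-table enumeration."""
    y = list(y_bins)
    z = list(z_labels)
    n = len(y)
    total = 0.0
    for yy in sorted(set(y)):
        py = sum(1 for a in y if a == yy) / n
        for zz in sorted(set(z)):
            pz = sum(1 for b in z if b == zz) / n
            pyz = sum(1 for a, b in zip(y, z) if a == yy and b == zz) / n
            if pyz > 0:
                total += pyz * pyz / (py * pz)
    return total


def parzen_class_densities(train_X, train_y, sigmas, x) -> dict:
    """Per-class mean Gaussian-kernel density, equal priors, plain loops.

    ``sigmas`` maps class -> smoothing factor; kernel exp(-d^2 / sigma^2).
    """
    out = {}
    for c in sorted(set(int(v) for v in train_y)):
        vals = []
        for xc, yc in zip(train_X, train_y):
            if int(yc) == c:
                d2 = sum((float(a) - float(b)) ** 2 for a, b in zip(x, xc))
                vals.append(math.exp(-d2 / float(sigmas[c]) ** 2))
        out[c] = sum(vals) / len(vals)
    return out


def parzen_predict(train_X, train_y, sigmas, x) -> int:
    """Argmax of the oracle densities; ties to the lower class label."""
    dens = parzen_class_densities(train_X, train_y, sigmas, x)
    best_c, best_v = None, -1.0
    for c in sorted(dens):
        if dens[c] > best_v:
            best_c, best_v = c, dens[c]
    return best_c


def on_some_smote_segment(s, minority, neighbor_sets, tol=1e-9) -> bool:
    """True iff ``s`` lies on a segment [c, q] with q a k-neighbor of c."""
    for ci, c in enumerate(minority):
        for qi in neighbor_sets[ci]:
            q = minority[qi]
            d = q - c
            dd = float(np.dot(d, d))
            if dd == 0.0:
                if np.allclose(s, c, atol=tol):
                    return True
                continue
            u = float(np.dot(s - c, d) / dd)
            if -tol <= u <= 1 + tol and np.linalg.norm(s - (c + u * d)) <= tol:
                return True
    return False


def knn_neighbor_sets(minority: np.ndarray, k: int) -> list[list[int]]:
    """Brute-force k nearest minority neighbors (self excluded)."""
    out = []
    for i in range(len(minority)):
        d = [(float(np.linalg.norm(minority[i] - minority[j])), j)
             for j in range(len(minority)) if j != i]
        d.sort()
        out.append([j for _, j in d[:k]])
    return out


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def desk_grid():
    return make_uniform_grid(50.0, 4000.0, 50.0)


@pytest.fixture
def small_dataset(desk_grid) -> SpectralDataset:
    """Default-conditions synthetic cohort (41 metastatic / 178 not)."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture
def banded_dataset(desk_grid) -> SpectralDataset:
    """Class effect confined to the 3500-4000 MHz band."""
    return generate(GeneratorConfig(seed=11, informative_band_mhz=(3500.0, 4000.0)))


def separable_benchmark(seed: int, n_per_class: int = 60, delta_sd: float = 4.0):
    """Two well-separated Gaussian classes (class-mean gap = delta_sd x sd)."""
    rng = np.random.default_rng(seed)
    y = np.array([int(ClassLabel.NEGATIVE)] * n_per_class + [int(ClassLabel.POSITIVE)] * n_per_class)
    X = rng.normal(loc=delta_sd * y[:, None], scale=1.0, size=(2 * n_per_class, 2))
    return X, y


def write_csv(path, header_freqs, rows):
    """Write a spectral CSV from (sample_id, label, values) tuples."""
    lines = ["sample_id,label," + ",".join(f"{f}MHz" for f in header_freqs)]
    for sid, lab, vals in rows:
        lines.append(f"{sid},{lab}," + ",".join(str(v) for v in vals))
    path.write_text("\n".join(lines) + "\n")
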