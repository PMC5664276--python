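"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lvquant.phantom import LesionWedge, PhantomSpec, StudySpec, generate_phantom


# ---------------------------------------------------------------------------
# independent oracles (deliberately written apart from the implementation)
# ---------------------------------------------------------------------------

def brute_force_otsu(counts: np.ndarray, edges: np.ndarray) -> float:
    """Exhaustive minimizer of the within-class variance over all bin cuts.

    Evaluates every cut k (classes bins[0..k] vs bins[k+1..]) independently
    of the implementation and returns the threshold as the mean upper edge
    of the tied minimizing cuts (the midpoint of an empty-bin plateau).
    """
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (np.asarray(edges)[:-1] + np.asarray(edges)[1:])
    total = counts.sum()
    wcvs = []
    for k in range(len(counts) - 1):
        c0, c1 = counts[: k + 1], counts[k + 1:]
        w0, w1 = c0.sum(), c1.sum()
        if w0 == 0 or w1 == 0:
            wcvs.append(np.inf)
            continue
        v0c, v1c = centers[: k + 1], centers[k + 1:]
        mu0 = (c0 * v0c).sum() / w0
        mu1 = (c1 * v1c).sum() / w1
        var0 = (c0 * (v0c - mu0) ** 2).sum() / w0
        var1 = (c1 * (v1c - mu1) ** 2).sum() / w1
        wcvs.append((w0 * var0 + w1 * var1) / total)
    wcvs = np.array(wcvs)
    best = wcvs.min()
    tied = np.nonzero(wcvs <= best + 1e-10 * max(best, 1e-30))[0]
    return float(np.mean([edges[k + 1] for k in tied]))


def classify_pixel(x: int, y: int, spec: PhantomSpec) -> str:
    """Scalar per-pixel phantom classification: background/myocardium/lesion."""
    dx, dy = x - spec.center[0], y - spec.center[1]
    r = np.hypot(dx, dy)
    if not (spec.r_endo <= r < spec.r_epi):
        return "background"
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    for w in spec.wedges:
        r_out = spec.r_endo + w.transmurality * (spec.r_epi - spec.r_endo)
        if (theta - w.start_angle) % 360.0 < w.span and r < r_out:
            return "lesion"
    return "myocardium"


def sector_of_pixel(x: int, y: int, center: tuple[float, float]) -> int:
    """Scalar atan2 sector assignment oracle (1-degree half-open bins)."""
    theta = np.degrees(np.arctan2(y - center[1], x - center[0])) % 360.0
    return int(np.floor(theta)) % 360


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def wedge_phantom():
    """Noiseless 90-degree transmural wedge phantom and its ground truth."""
    spec = PhantomSpec(wedges=(LesionWedge(start_angle=20.0, span=90.0),))
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def small_study():
    """A small seeded 3-subject study (images, truths, truth table)."""
    from lvquant.phantom import generate_study

    spec = StudySpec(n_subjects=3, seed=7)
    return spec, *generate_study(spec)
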