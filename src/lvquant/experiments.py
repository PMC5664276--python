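"""Reusable phantom experiments behind the analysis drivers and validation.

Each function runs one self-contained computation — wedge-recovery
accuracy, Otsu-vs-exhaustive agreement, the permutation calibration of the
repeated-measures F test, or the full default study emulation — and
returns plain tables/dicts, so drivers, tests and validation scripts all
share the same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lvquant.phantom import LesionWedge, PhantomSpec, StudySpec, generate_study
from lvquant.pipeline import compare_study, quantify_slice
from lvquant.roi import MyocardialMask, lv_center, midline_lesion_fraction
from lvquant.sectors import sector_quantify, sector_values
from lvquant.stats import rm_anova_f
from lvquant.threshold import (
    IntensityHistogram,
    normalize_intensity,
    otsu_threshold,
    quantify_area,
)


def wedge_recovery(
    n_geometries: int = 20,
    noise_sigma: float = 0.0,
    lesion_level: float = 0.9,
    span_range: tuple[float, float] = (30.0, 300.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Measure transmural wedge phantoms with all three methods.

    Spans are uniform over ``span_range``; the analytic ground truth of a
    transmural wedge is span/360.  Returns one row per phantom with the
    true fraction and the area-, sector- and midline-based estimates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_geometries):
        span = float(rng.uniform(*span_range))
        start = float(rng.uniform(0.0, 360.0))
        spec = PhantomSpec(
            wedges=(LesionWedge(start, span, 1.0),),
            lesion_level=lesion_level,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, truth = generate_phantom_cached(spec)
        mask = MyocardialMask(truth.myocardium_mask, lv_center(truth.myocardium_mask))
        polarity = "hyper" if lesion_level > spec.myocardium_level else "hypo"
        area_pct, _, _ = quantify_area(img, mask, polarity)
        norm = normalize_intensity(img, mask)
        sector_pct = sector_quantify(sector_values(norm, mask), polarity).fraction
        midline_pct = midline_lesion_fraction(mask, truth.lesion_mask)
        rows.append(
            {
                "phantom": i,
                "span_deg": span,
                "true_area_pct": truth.true_fraction_area,
                "true_angle_pct": truth.true_fraction_angle,
                "area_pct": area_pct,
                "sector_pct": sector_pct,
                "midline_pct": midline_pct,
            }
        )
    return pd.DataFrame(rows)


def generate_phantom_cached(spec: PhantomSpec):
    # single indirection point so batch drivers could memoize if ever needed
    from lvquant.phantom import generate_phantom

    return generate_phantom(spec)


def otsu_oracle_agreement(n_histograms: int = 100, max_bins: int = 64, seed: int = 0) -> dict:
    """Compare the histogram Otsu against an exhaustive scan on random data.

    For each random histogram the exhaustive scan recomputes the
    between-/within-class variances per cut from scratch; agreement means
    the same (tie-averaged) threshold to 1e-12 and exact conservation
    sigma_b^2 + sigma_w^2 = total variance at every candidate cut.
    """
    rng = np.random.default_rng(seed)
    n_match = 0
    max_conservation_error = 0.0
    for _ in range(n_histograms):
        n_bins = int(rng.integers(2, max_bins + 1))
        counts = rng.integers(0, 400, size=n_bins)
        if (counts > 0).sum() < 2:
            counts[rng.choice(n_bins, 2, replace=False)] = 1
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        hist = IntensityHistogram(counts=counts, bin_edges=edges)
        res = otsu_threshold(hist)

        # exhaustive recomputation, cut by cut
        centers = hist.bin_centers
        c = counts.astype(float)
        total = c.sum()
        wcv = np.full(n_bins - 1, np.inf)
        bcv = np.full(n_bins - 1, -np.inf)
        for k in range(n_bins - 1):
            w0, w1 = c[: k + 1].sum(), c[k + 1:].sum()
            if w0 == 0 or w1 == 0:
                continue
            mu0 = (c[: k + 1] * centers[: k + 1]).sum() / w0
            mu1 = (c[k + 1:] * centers[k + 1:]).sum() / w1
            v0 = (c[: k + 1] * (centers[: k + 1] - mu0) ** 2).sum() / w0
            v1 = (c[k + 1:] * (centers[k + 1:] - mu1) ** 2).sum() / w1
            wcv[k] = (w0 * v0 + w1 * v1) / total
            bcv[k] = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        best = wcv.min()
        tied = np.nonzero(wcv <= best + 1e-10 * max(best, 1e-30))[0]
        expected = float(np.mean(edges[tied + 1]))
        if abs(res.threshold - expected) <= 1e-12:
            n_match += 1

        mu = (c * centers).sum() / total
        total_var = (c * (centers - mu) ** 2).sum() / total
        ok = np.isfinite(wcv)
        max_conservation_error = max(
            max_conservation_error,
            float(np.abs(res.sigma_b2[ok] + res.sigma_w2[ok] - total_var).max()),
        )
    return {
        "n_histograms": n_histograms,
        "agreement_rate": n_match / n_histograms,
        "max_conservation_error": max_conservation_error,
    }


def permutation_type1_error(
    n_permutations: int = 1000, n_units: int = 56, k: int = 3, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Calibration of the repeated-measures F test under a permutation null.

    Starting from exchangeable (iid normal) per-slice data, condition
    labels are permuted uniformly within each slice; the empirical rate of
    parametric p < alpha estimates the type-I error.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    base = rng.normal(40.0, 10.0, size=(n_units, k))
    hits = 0
    for _ in range(n_permutations):
        perm = base.copy()
        for row in perm:
            rng.shuffle(row)
        f, d1, d2 = rm_anova_f(perm)
        if sps.f.sf(f, d1, d2) < alpha:
            hits += 1
    return {
        "n_permutations": n_permutations,
        "alpha": alpha,
        "type1_error": hits / n_permutations,
    }


def run_default_study(seed: int = 0, n_subjects: int = 14) -> tuple[pd.DataFrame, dict]:
    """Generate the default study in memory, quantify every slice with all
    methods, and return (study table, comparison report)."""
    spec = StudySpec(n_subjects=n_subjects, seed=seed)
    images, truths, truth_table = generate_study(spec)
    polarity = {m.name: m.polarity for m in spec.modalities}
    rows: list[dict] = []
    for img, truth in zip(images, truths):
        rows.extend(
            quantify_slice(
                img,
                truth.myocardium_mask,
                polarity[img.modality],
                lesion_truth=truth.lesion_mask,
                methods=("area", "sector", "midline"),
            )
        )
    table = pd.DataFrame(rows)
    truth_rows = truth_table.rename(columns={"true_area_pct": "enhancement_pct"})[
        ["subject", "slice", "modality", "enhancement_pct"]
    ].assign(method="truth", threshold=np.nan, n_total=np.nan, n_enhanced=np.nan)
    table = pd.concat([table, truth_rows[table.columns]], ignore_index=True)
    return table, compare_study(table)
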