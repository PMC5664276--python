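"""End-to-end study orchestration: simulate -> quantify -> compare.

These functions carry the whole phantom study through disk: the simulator
writes per-slice NIfTI images with paired mask PNGs and a ground-truth
TSV; quantification reads them back and produces the long-format study
table; the comparison step runs the modality and method-agreement
statistics and writes a report.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from lvquant import io as lvio
from lvquant.io import ShortAxisImage
from lvquant.phantom import StudySpec, generate_study
from lvquant.roi import MyocardialMask, lv_center, midline_lesion_fraction
from lvquant.sectors import radial_profile_export, sector_quantify, sector_values
from lvquant.stats import bland_altman, correlate, paired_modalities_test
from lvquant.threshold import normalize_intensity, quantify_area

#: polarity of each default modality: the lesion is bright on late
#: gadolinium enhancement and dark on Mn- or nanoparticle-enhanced images
DEFAULT_POLARITY = {"LGE": "hyper", "MEMRI": "hypo", "MNP": "hypo"}

METHODS = ("area", "sector", "midline")


def simulate_study(spec: StudySpec, outdir: str | Path) -> Path:
    """Generate a phantom study and write it under ``outdir``.

    Layout: ``images/<subject>_<modality>_s<slice>.nii``, paired
    ``masks/..._myo.png`` / ``..._lesion.png`` (0/255), and ``truth.tsv``
    with the per-slice true area and angle fractions.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    images, truths, truth_table = generate_study(spec)
    for img, truth in zip(images, truths):
        stem = f"{img.subject_id}_{img.modality}_s{img.slice_index}"
        lvio.write_image(img, outdir / "images" / f"{stem}.nii")
        for suffix, m in (("myo", truth.myocardium_mask), ("lesion", truth.lesion_mask)):
            lvio.write_image(
                ShortAxisImage((m.astype(np.uint8) * 255)),
                outdir / "masks" / f"{stem}_{suffix}.png",
            )
    truth_table.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    return outdir


def quantify_slice(
    image: ShortAxisImage,
    myo_mask: np.ndarray,
    polarity: str,
    lesion_truth: np.ndarray | None = None,
    methods: tuple[str, ...] = ("area", "sector"),
    n_bins: int = 256,
    angle_offset: float = 0.0,
    profile_path: str | Path | None = None,
) -> list[dict]:
    """Quantify one slice with the requested methods.

    'area' and 'sector' segment the image by Otsu thresholding; 'midline'
    is the histology-analog mid-wall length fraction and requires the
    ground-truth lesion mask.  Returns one row dict per method.
    """
    center = lv_center(np.asarray(myo_mask, dtype=bool))
    mask = MyocardialMask(mask=myo_mask, center=center)
    meta = {
        "subject": image.subject_id,
        "slice": image.slice_index,
        "modality": image.modality,
    }
    rows = []
    for method in methods:
        if method == "area":
            pct, otsu, lesion = quantify_area(image, mask, polarity, n_bins=n_bins)
            rows.append(
                meta
                | {
                    "method": "area",
                    "enhancement_pct": pct,
                    "threshold": otsu.threshold if otsu else np.nan,
                    "n_total": mask.n_pixels,
                    "n_enhanced": int(lesion.sum()),
                }
            )
        elif method == "sector":
            norm = normalize_intensity(image, mask)
            profile = sector_values(norm, mask, angle_offset=angle_offset)
            quant = sector_quantify(profile, polarity)
            if profile_path is not None:
                radial_profile_export(profile, quant, profile_path)
            rows.append(
                meta
                | {
                    "method": "sector",
                    "enhancement_pct": quant.fraction,
                    "threshold": quant.threshold,
                    "n_total": quant.valid_sectors,
                    "n_enhanced": quant.enhanced_sectors,
                }
            )
        elif method == "midline":
            if lesion_truth is None:
                raise ValueError("midline method requires the ground-truth lesion mask")
            pct = midline_lesion_fraction(mask, lesion_truth)
            rows.append(
                meta
                | {
                    "method": "midline",
                    "enhancement_pct": pct,
                    "threshold": np.nan,
                    "n_total": np.nan,
                    "n_enhanced": np.nan,
                }
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return rows


def quantify_study_dir(
    study_dir: str | Path,
    polarity_map: dict[str, str] | None = None,
    methods: tuple[str, ...] = METHODS,
    n_bins: int = 256,
    angle_offset: float = 0.0,
    allow_empty: bool = False,
    profiles_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Quantify every image of a simulated (or equivalently laid-out) study.

    Appends 'truth' rows from ``truth.tsv`` when present, so downstream
    statistics can correlate estimates against ground truth.
    """
    study_dir = Path(study_dir)
    polarity_map = polarity_map or DEFAULT_POLARITY
    image_files = sorted((study_dir / "images").glob("*.nii")) if (
        study_dir / "images"
    ).is_dir() else []
    rows: list[dict] = []
    n_warn = 0
    for f in image_files:
        image = lvio.read_image(f)
        stem = f.name[: -len(".nii")]
        myo_path = study_dir / "masks" / f"{stem}_myo.png"
        if not myo_path.exists():
            warnings.warn(f"no myocardium mask for {f.name}; row skipped", stacklevel=2)
            n_warn += 1
            continue
        myo = lvio.read_image(myo_path).pixels > 0
        lesion_path = study_dir / "masks" / f"{stem}_lesion.png"
        lesion = lvio.read_image(lesion_path).pixels > 0 if lesion_path.exists() else None
        polarity = polarity_map.get(image.modality)
        if polarity is None:
            raise ValueError(f"no polarity configured for modality {image.modality!r}")
        use_methods = tuple(m for m in methods if m != "midline" or lesion is not None)
        profile_path = None
        if profiles_dir is not None and "sector" in use_methods:
            profile_path = Path(profiles_dir) / f"{stem}_profile.tsv"
        rows.extend(
            quantify_slice(
                image,
                myo,
                polarity,
                lesion_truth=lesion,
                methods=use_methods,
                n_bins=n_bins,
                angle_offset=angle_offset,
                profile_path=profile_path,
            )
        )
    if not image_files and not allow_empty:
        raise FileNotFoundError(f"no images found under {study_dir / 'images'}")
    table = pd.DataFrame(rows, columns=lvio.TABLE_COLUMNS)
    truth_path = study_dir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        truth_rows = truth.rename(columns={"true_area_pct": "enhancement_pct"})[
            ["subject", "slice", "modality", "enhancement_pct"]
        ].assign(method="truth", threshold=np.nan, n_total=np.nan, n_enhanced=np.nan)
        table = pd.concat([table, truth_rows[table.columns]], ignore_index=True)
    return table


def compare_study(table: pd.DataFrame) -> dict:
    """Run the full statistical comparison on a long-format study table.

    Sections: per-method modality comparison (means +/- SD, RM-ANOVA,
    Tukey), area-vs-sector Bland-Altman agreement per modality, pairwise
    cross-modality Pearson/Spearman correlations, and estimate-vs-truth
    correlations when truth rows are present.  Sections that lack the
    required rows are omitted with a notice.
    """
    report: dict = {"notices": []}
    methods = sorted(table["method"].unique())
    modalities = sorted(table["modality"].unique())

    report["modality_comparison"] = {}
    for method in methods:
        if method == "truth":
            continue
        sub = table[table["method"] == method]
        if sub["modality"].nunique() < 2:
            report["notices"].append(f"{method}: <2 modalities, comparison skipped")
            continue
        res = paired_modalities_test(table, method=method)
        report["modality_comparison"][method] = {
            "means": res.group_means,
            "sds": res.group_sds,
            "F": res.f_statistic,
            "p": res.p_value,
            "tukey_p": {f"{a} vs {b}": p for (a, b), p in res.tukey_p.items()},
            "shapiro_p": res.shapiro_p,
            "n_slices": res.n_units,
        }

    report["method_agreement"] = {}
    if {"area", "sector"} <= set(methods):
        for modality in modalities:
            wide = _pivot_pair(table, modality, "area", "sector")
            if len(wide) >= 2:
                ba = bland_altman(wide.to_numpy())
                report["method_agreement"][modality] = {
                    "bias": ba.bias,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "n": ba.n_pairs,
                }
    else:
        report["notices"].append("area-vs-sector Bland-Altman skipped: need both methods")

    report["cross_modality_correlation"] = {}
    for method in methods:
        if method == "truth":
            continue
        for i, a in enumerate(modalities):
            for b in modalities[i + 1:]:
                wide = _pivot_modalities(table, method, a, b)
                if len(wide) >= 3:
                    pear = correlate(wide[a], wide[b], "pearson")
                    spear = correlate(wide[a], wide[b], "spearman")
                    report["cross_modality_correlation"][f"{method}:{a} vs {b}"] = {
                        "pearson_r": pear.r,
                        "pearson_p": pear.p_value,
                        "spearman_r": spear.r,
                        "spearman_p": spear.p_value,
                        "n": pear.n,
                    }

    if "truth" in methods:
        report["truth_correlation"] = {}
        for method in methods:
            if method == "truth":
                continue
            for modality in modalities:
                wide = _pivot_pair(table, modality, method, "truth")
                if len(wide) >= 3:
                    pear = correlate(wide.iloc[:, 0], wide.iloc[:, 1], "pearson")
                    report["truth_correlation"][f"{method}:{modality}"] = {
                        "pearson_r": pear.r,
                        "pearson_p": pear.p_value,
                        "mean_abs_error": float(
                            (wide.iloc[:, 0] - wide.iloc[:, 1]).abs().mean()
                        ),
                        "n": pear.n,
                    }
    return report


def _pivot_pair(table: pd.DataFrame, modality: str, m1: str, m2: str) -> pd.DataFrame:
    sub = table[(table["modality"] == modality) & (table["method"].isin([m1, m2]))]
    wide = sub.pivot_table(
        index=["subject", "slice"], columns="method", values="enhancement_pct", aggfunc="first"
    )
    if m1 not in wide.columns or m2 not in wide.columns:
        return pd.DataFrame(columns=[m1, m2])
    return wide[[m1, m2]].dropna()


def _pivot_modalities(table: pd.DataFrame, method: str, a: str, b: str) -> pd.DataFrame:
    sub = table[(table["method"] == method) & (table["modality"].isin([a, b]))]
    wide = sub.pivot_table(
        index=["subject", "slice"], columns="modality", values="enhancement_pct", aggfunc="first"
    )
    if a not in wide.columns or b not in wide.columns:
        return pd.DataFrame(columns=[a, b])
    return wide[[a, b]].dropna()


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write the comparison report as JSON plus a flat TSV of key numbers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = []
    for method, d in report.get("modality_comparison", {}).items():
        for mod, mean in d["means"].items():
            rows.append(("modality_mean", f"{method}:{mod}", mean))
        rows.append(("anova_p", method, d["p"]))
    for mod, d in report.get("method_agreement", {}).items():
        rows.append(("bland_altman_bias", mod, d["bias"]))
    for key, d in report.get("cross_modality_correlation", {}).items():
        rows.append(("pearson_r", key, d["pearson_r"]))
    pd.DataFrame(rows, columns=["quantity", "key", "value"]).to_csv(
        outdir / "report.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return outdir / "report.json"
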