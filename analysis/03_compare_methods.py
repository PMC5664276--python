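#!/usr/bin/env python
"""Statistical comparison of modalities and measurement methods.

Reads results/study_table.tsv and runs the study's statistics: paired
modality comparison (repeated-measures ANOVA + Tukey), area-vs-sector
Bland-Altman agreement, cross-modality correlations, and estimate-vs-truth
correlations.  Writes results/report.json (+ .tsv) and prints the
findings.
"""

from pathlib import Path

from lvquant.io import read_results_table
from lvquant.pipeline import compare_study, write_report

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    path = ROOT / "results" / "study_table.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_quantify_lesions.py first")
    table = read_results_table(path)
    report = compare_study(table)
    write_report(report, ROOT / "results")

    comp = report["modality_comparison"]["area"]
    print("area-based modality comparison (RM-ANOVA):")
    for mod, mean in comp["means"].items():
        print(f"  {mod}: {mean:.1f} +/- {comp['sds'][mod]:.1f} %")
    print(f"  F = {comp['F']:.1f}, p = {comp['p']:.2e}; Tukey: "
          + ", ".join(f"{k} p={v:.2g}" for k, v in comp["tukey_p"].items()))

    print("area vs sector agreement (Bland-Altman bias [limits]):")
    for mod, d in report["method_agreement"].items():
        print(f"  {mod}: {d['bias']:+.2f} [{d['loa_low']:+.2f}, {d['loa_high']:+.2f}] pct points")

    print("cross-modality correlations (area-based):")
    for key, d in report["cross_modality_correlation"].items():
        if key.startswith("area:"):
            print(f"  {key[5:]}: r = {d['pearson_r']:.2f} (p = {d['pearson_p']:.2g})")
    print("report written to results/report.json")


if __name__ == "__main__":
    main()
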