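#!/usr/bin/env python
"""Classify every cohort by leave-one-out cross-validated MLP.

Runs the confidence-thresholded perceptron (3 hidden nodes, 50,000
iteration cap, confidence level 0.05) with per-fold refitting of
binning, variance filter and Z-scaling.  The two-class cohort is run
for all four feature-set variants (MSD alone and fused with the
plantar-test and/or von Frey columns); the four-class and null cohorts
on spectral data alone.  Writes per-cohort prediction tables and a
global ``results/loocv_summary.csv``; UNKNOWN predictions count as
errors in every success percentage.
"""

import sys
from pathlib import Path

import pandas as pd

from painprint.ann import MLPConfig, classification_report
from painprint.cli import _load_cohort_dir
from painprint.pipeline import VARIANTS, loocv_peaklists
from painprint.preprocess import PreprocessConfig, preprocess_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path("results/cohorts")

rows = []
for cohort_dir in sorted(p for p in ROOT.iterdir() if p.is_dir()):
    spectra, blanks, behavior, labels = _load_cohort_dir(cohort_dir)
    peaklists, _ = preprocess_cohort(spectra, blanks, PreprocessConfig())
    variants = VARIANTS if cohort_dir.name == "two_class" else VARIANTS[:1]
    for name, include in variants:
        cv = loocv_peaklists(peaklists, labels, MLPConfig(seed=SEED),
                             behavior, include=include)
        text, _ = classification_report(cv)
        tag = name.replace("+", "_")
        pd.DataFrame({"sample_id": cv.sample_ids, "true": cv.true_labels,
                      "predicted": cv.predicted}).to_csv(
            cohort_dir / f"loocv_{tag}.csv", index=False)
        rows.append({"cohort": cohort_dir.name, "variant": name,
                     "success_pct": round(cv.success_percentage),
                     "n_correct": cv.n_correct, "n_unknown": cv.n_unknown,
                     "n": cv.n})
        print(f"{cohort_dir.name} / {name}: {text.splitlines()[0]}")

summary = pd.DataFrame(rows)
summary.to_csv("results/loocv_summary.csv", index=False)
print("\n" + summary.to_string(index=False))
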