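#!/usr/bin/env python
"""Preprocess raw spectra into per-sample peak lists.

For every cohort written by ``01_simulate_cohorts.py``: Savitzky-Golay
smoothing, Loess baseline subtraction, base-peak normalization to 100%,
rigid m/z alignment, peak detection against a robust noise floor,
majority-rule merging of the triplicate spots, and exclusion of matrix
peaks identified from the blanks.  Writes ``peaks.csv`` per cohort and
prints how many peaks survive each sample.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from painprint.cli import _load_cohort_dir
from painprint.preprocess import PreprocessConfig, preprocess_cohort

ROOT = Path("results/cohorts")

for cohort_dir in sorted(p for p in ROOT.iterdir() if p.is_dir()):
    spectra, blanks, _, labels = _load_cohort_dir(cohort_dir)
    peaklists, blank_pls = preprocess_cohort(spectra, blanks, PreprocessConfig())
    rows = [(sid, m, v) for sid, pl in sorted(peaklists.items())
            for m, v in zip(pl.mz, pl.intensity)]
    pd.DataFrame(rows, columns=["sample_id", "mz", "rel_intensity"]).to_csv(
        cohort_dir / "peaks.csv", index=False, float_format="%.6g")
    counts = [len(pl) for pl in peaklists.values()]
    print(f"{cohort_dir.name}: {len(peaklists)} samples, "
          f"{np.median(counts):.0f} peaks/sample (range {min(counts)}-{max(counts)}), "
          f"{np.median([len(b) for b in blank_pls]):.0f} blank peaks")
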