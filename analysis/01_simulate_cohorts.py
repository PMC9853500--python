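#!/usr/bin/env python
"""Simulate the study cohorts.

Generates three synthetic serum-fingerprint cohorts with known ground
truth and writes them under ``results/cohorts/``:

* ``two_class``  — control vs pain model, 15 animals/group, triplicates;
* ``four_class`` — the four pain models (CCI, SCI, RIM, ASI), 15/group;
* ``null``       — two groups with effect size 1 (labels carry no
  spectral information), the negative control for the classifier.

Each cohort directory holds per-spectrum delimited files, a manifest,
labels, raw behavioral records and the ground-truth JSON.
"""

import sys
from pathlib import Path

import numpy as np

from painprint.synthetic import CohortConfig, generate_cohort, write_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/cohorts")

COHORTS = {
    "two_class": CohortConfig(n_per_group=15, seed=SEED),
    "four_class": CohortConfig(n_per_group=15, groups=("CCI", "SCI", "RIM", "ASI"),
                               seed=SEED + 1),
    "null": CohortConfig(n_per_group=15, effect_size=1.0, seed=SEED + 2),
}

for name, cfg in COHORTS.items():
    spectra, blanks, behavior, truth = generate_cohort(cfg)
    write_cohort(OUT / name, spectra, blanks, behavior, truth)
    n_info = len(truth.informative_peak_positions)
    low = np.mean(truth.informative_peak_positions < 1_000)
    print(f"{name}: {len(spectra)} sample spectra ({cfg.n_replicates} replicates x "
          f"{len(truth.labels)} animals), {len(blanks)} blanks; "
          f"{n_info} informative peaks ({low:.0%} below 1,000 Da), "
          f"effect size {cfg.effect_size}")
print(f"written to {OUT}/")
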