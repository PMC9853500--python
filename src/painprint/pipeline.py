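"""End-to-end experiment orchestration.

One experiment mirrors the study layout: simulate (or load) a cohort,
preprocess spectra into per-sample peak lists, derive the behavioral
outcomes, then run leave-one-out cross-validation for each feature-set
variant — mass-spectrum data alone (MSD) and fused with plantar-test
(PTD) and/or von Frey (VFD) columns — and write a summary of success
percentages.

Inside LOOCV the cross-sample steps (peak binning, variance filter,
Z-scaling) are refit on the training fold only; ``global_prep=True``
reproduces the leakage-prone variant that fits them once on all
samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ann import (CVResult, MLPConfig, classification_report, fold_seed,
                  predict_with_confidence, train)
from .behavior import BehaviorRecord
from .features import (FeatureMatrix, apply_z_scale, bin_peaks, fuse_behavior,
                       map_to_bins, pca_scores, variance_filter, z_scale)
from .preprocess import PeakList, PreprocessConfig, preprocess_cohort
from .synthetic import CohortConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "VARIANTS", "loocv_peaklists", "build_feature_matrix",
           "run_experiment"]

#: Feature-set variants reported per experiment: spectral data alone and
#: fused with each behavioral column.
VARIANTS: tuple[tuple[str, frozenset], ...] = (
    ("MSD", frozenset()),
    ("MSD+PTD", frozenset({"PTD"})),
    ("MSD+VFD", frozenset({"VFD"})),
    ("MSD+PTD+VFD", frozenset({"PTD", "VFD"})),
)


@dataclass
class RunConfig:
    """Everything one experiment needs, with a single master seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    bin_tolerance: float = 3.0
    variance_threshold: float = 1.0
    name: str = "experiment"
    master_seed: int = 0
    global_prep: bool = False
    include_behavior_variants: bool = True

    def __post_init__(self) -> None:
        # one master seed drives every stochastic stage
        self.cohort.seed = int(np.random.SeedSequence([self.master_seed, 1])
                               .generate_state(1)[0] % (2 ** 31))
        self.mlp.seed = int(np.random.SeedSequence([self.master_seed, 2])
                            .generate_state(1)[0] % (2 ** 31))


def build_feature_matrix(peaklists: dict[str, PeakList], labels: dict[str, str],
                         behavior: list[BehaviorRecord] | None = None,
                         include: frozenset = frozenset(),
                         bin_tolerance: float = 3.0) -> FeatureMatrix:
    """Bin peak lists across samples and optionally fuse behavior (raw scale)."""
    pls = [peaklists[s] for s in sorted(peaklists)]
    matrix = bin_peaks(pls, labels, bin_tolerance)
    if include:
        if behavior is None:
            raise ValueError("behavioral variant requested but no records given")
        matrix = fuse_behavior(matrix, behavior, include)
    return matrix


def loocv_peaklists(peaklists: dict[str, PeakList], labels: dict[str, str],
                    mlp_config: MLPConfig,
                    behavior: list[BehaviorRecord] | None = None,
                    include: frozenset = frozenset(),
                    bin_tolerance: float = 3.0, variance_threshold: float = 1.0,
                    global_prep: bool = False) -> CVResult:
    """Leakage-safe LOOCV starting from per-sample peak lists.

    Per fold: bin the training peak lists, variance-filter, fuse
    behavior, Z-scale, train the network with a fold seed; the held-out
    sample's peaks are projected onto the training bins and transformed
    with the stored scaling before prediction.
    """
    sids = sorted(peaklists)
    n = len(sids)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    labs = [labels[s] for s in sids]
    counts = pd.Series(labs).value_counts()
    if (counts < 2).any():
        raise ValueError(f"class(es) {counts[counts < 2].index.tolist()} "
                         "have a single member")
    recs = {r.sample_id: r for r in (behavior or [])}

    if global_prep:
        matrix = build_feature_matrix(peaklists, labels, behavior, include, bin_tolerance)
        filtered = variance_filter(matrix, variance_threshold)
        scaled = z_scale(filtered)

    preds, fcounts = [], []
    for i, sid in enumerate(sids):
        cfg = MLPConfig(**{**mlp_config.__dict__, "seed": fold_seed(mlp_config.seed, i)})
        if global_prep:
            keep = [j for j in range(n) if j != i]
            train_m = FeatureMatrix(scaled.values[keep], list(scaled.feature_ids),
                                    [sids[j] for j in keep], [labs[j] for j in keep],
                                    "z_scaled")
            x_test = scaled.values[i]
        else:
            fold_pls = {s: peaklists[s] for s in sids if s != sid}
            matrix = build_feature_matrix(fold_pls, labels, behavior, include, bin_tolerance)
            filtered = variance_filter(matrix, variance_threshold)
            train_m = z_scale(filtered)
            spectral = filtered.spectral_mask()
            x_spec = map_to_bins(peaklists[sid], filtered.bin_centers, bin_tolerance)
            extra = []
            for tag in ("PTD", "VFD"):
                if tag in include:
                    rec = recs.get(sid)
                    if rec is None:
                        raise ValueError(f"missing behavioral record for {sid}")
                    extra.append(rec.derived_latency_mean if tag == "PTD"
                                 else rec.derived_threshold_50)
            x_raw = np.concatenate([x_spec, np.asarray(extra, float)]) if extra else x_spec
            assert len(x_raw) == filtered.n_features, (len(x_raw), filtered.n_features)
            x_test = apply_z_scale(x_raw, train_m.scaler)
        model = train(cfg, train_m)
        preds.append(predict_with_confidence(model, x_test))
        fcounts.append(train_m.n_features)
    return CVResult(sample_ids=sids, true_labels=labs, predicted=preds,
                    classes=sorted(set(labs)), feature_counts=fcounts)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(run_config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate, preprocess, classify, and write a run directory.

    The directory contains the cohort (manifest + spectra), the merged
    peak tables, the raw feature matrix, PCA scores, per-variant LOOCV
    predictions and confusion tables, a ``summary.csv`` of success
    percentages, and a provenance record.  Reruns with the same config
    and seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = run_config

    spectra, blanks, behavior, truth = generate_cohort(cfg.cohort)
    write_cohort(out / "cohort", spectra, blanks, behavior, truth)
    peaklists, _ = preprocess_cohort(spectra, blanks, cfg.preprocess)

    # merged peak table
    rows = [(sid, m, v) for sid, pl in sorted(peaklists.items())
            for m, v in zip(pl.mz, pl.intensity)]
    pd.DataFrame(rows, columns=["sample_id", "mz", "rel_intensity"]).to_csv(
        out / "peaks.csv", index=False, float_format="%.6g")

    matrix = build_feature_matrix(peaklists, truth.labels,
                                  bin_tolerance=cfg.bin_tolerance)
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids)
    df.insert(0, "label", matrix.labels)
    df.to_csv(out / "feature_matrix_raw.csv", float_format="%.6g")

    filtered = variance_filter(matrix, cfg.variance_threshold)
    scaled = z_scale(filtered)
    k = min(3, scaled.n_samples - 1, scaled.n_features)
    pca = pca_scores(scaled, k=k)
    pc = pd.DataFrame(pca.scores, index=scaled.sample_ids,
                      columns=[f"PC{j + 1}" for j in range(k)])
    pc.insert(0, "label", scaled.labels)
    pc.to_csv(out / "pca_scores.csv", float_format="%.6g")

    variants = VARIANTS if cfg.include_behavior_variants else VARIANTS[:1]
    summary = []
    for name, include in variants:
        cv = loocv_peaklists(peaklists, truth.labels, cfg.mlp, behavior, include,
                             cfg.bin_tolerance, cfg.variance_threshold, cfg.global_prep)
        text, tab = classification_report(cv)
        tag = name.replace("+", "_")
        pd.DataFrame({"sample_id": cv.sample_ids, "true": cv.true_labels,
                      "predicted": cv.predicted}).to_csv(
            out / f"loocv_{tag}.csv", index=False)
        tab.to_csv(out / f"confusion_{tag}.csv")
        (out / f"report_{tag}.txt").write_text(text + "\n")
        summary.append({"variant": name, "success_pct": round(cv.success_percentage),
                        "n_correct": cv.n_correct, "n_unknown": cv.n_unknown,
                        "n": cv.n,
                        "median_n_features": int(np.median(cv.feature_counts))})
    pd.DataFrame(summary).to_csv(out / "summary.csv", index=False)

    with open(out / "provenance.json", "w") as fh:
        json.dump({"name": cfg.name, "master_seed": cfg.master_seed,
                   "config_sha256": _config_hash(cfg), "package_version": __version__,
                   "n_selected_features_full": filtered.n_features,
                   "explained_variance_ratio": pca.explained_variance_ratio.tolist()},
                  fh, indent=1)
    return out
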