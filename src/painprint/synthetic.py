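"""Synthetic serum-fingerprint cohorts with known ground truth.

The study this package supports acquired MALDI-TOF serum spectra from
mouse pathological-pain models; no spectra are deposited, so every
downstream stage is exercised on simulated cohorts instead.  The
generator emulates the features that matter to the pipeline:

* a shared peak library over the 0–10,000 Da acquisition window, with a
  subset of *informative* peaks whose intensities differ between classes
  by a multiplicative log-normal effect, concentrated in the low-mass
  (<1,000 Da) region where serum metabolite signals dominate;
* matrix (sinapinic-acid-like) peaks present in blanks and in every
  sample at low mass;
* Gaussian peak profiles with TOF-like width growing linearly in m/z,
  a smooth exponentially decaying baseline, additive Gaussian intensity
  noise floor-clipped at zero, and a small rigid m/z calibration jitter
  per acquisition;
* triplicate spotting (independent technical replicates per sample);
* behavioral records in which pain-model groups show reduced thermal
  withdrawal latencies and von Frey thresholds versus controls, while
  the model groups overlap with one another.

At ``effect_size = 1`` the class labels carry no spectral information by
construction: the class multipliers collapse to exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .behavior import BehaviorRecord, UpDownParams, simulate_updown
from .spectra import CohortManifest, Spectrum, write_spectrum

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "generate_behavior",
           "write_cohort", "CohortConfigError"]


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


#: Group names treated as healthy controls when assigning behavioral latents.
CONTROL_NAMES = frozenset({"control", "cnt", "sham", "saline", "ctrl"})


@dataclass
class CohortConfig:
    """Design of a simulated cohort.

    Parameters
    ----------
    n_per_group
        Animals per experimental group.
    groups
        Class labels; a label in {control, cnt, sham, saline, ctrl}
        (case-insensitive) gets healthy behavioral latents.
    peak_library_size
        Number of shared serum peaks in the library.
    mass_range
        Acquisition window in Da, within [0, 10,000].
    low_mass_fraction
        Fraction of class-informative peaks placed below 1,000 Da.
    effect_size
        Geometric spread of the per-class intensity multipliers on
        informative peaks (dimensionless, >= 1; 1 = no class signal).
    noise_sd
        Additive intensity noise SD, in the arbitrary units of the raw
        simulated signal (peak apexes are O(10-100)).
    baseline_amplitude
        Amplitude of the exponentially decaying baseline at 0 Da.
    mz_jitter_sd
        SD of the rigid per-acquisition m/z calibration shift, Da.
    n_replicates
        Spots per sample on the target plate (triplicate by default).
    n_matrix_peaks
        Matrix-derived peaks present in blanks and all samples.
    informative_fraction
        Fraction of library peaks that carry class information.
    grid_step
        Spacing of the simulated m/z grid, Da.
    """

    n_per_group: int = 15
    groups: tuple[str, ...] = ("control", "model")
    peak_library_size: int = 80
    mass_range: tuple[float, float] = (0.0, 10_000.0)
    low_mass_fraction: float = 0.6
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_amplitude: float = 30.0
    mz_jitter_sd: float = 1.0
    n_replicates: int = 3
    n_matrix_peaks: int = 8
    n_blanks: int = 3
    informative_fraction: float = 0.3
    biological_sigma: float = 0.15   # log-scale per-sample peak variation
    technical_sigma: float = 0.08    # log-scale per-replicate variation
    grid_step: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise CohortConfigError("groups must be nonempty")
        if len(set(self.groups)) != len(self.groups):
            raise CohortConfigError("duplicate group labels")
        if self.n_per_group <= 0 or self.n_replicates < 1 or self.peak_library_size <= 0:
            raise CohortConfigError("counts must be positive")
        lo, hi = self.mass_range
        if not (0.0 <= lo < hi <= 10_000.0):
            raise CohortConfigError("mass_range must lie within [0, 10,000] Da")
        if self.effect_size < 1.0:
            raise CohortConfigError("effect_size must be >= 1")
        if not (0.0 <= self.low_mass_fraction <= 1.0):
            raise CohortConfigError("low_mass_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.baseline_amplitude < 0 or self.mz_jitter_sd < 0:
            raise CohortConfigError("noise parameters must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    labels: dict[str, str]                       # sample_id -> class
    peak_positions: np.ndarray                   # full library, Da
    informative_peak_positions: np.ndarray       # subset carrying class signal
    class_multipliers: dict[str, np.ndarray]     # class -> per-library-peak factor
    matrix_peak_positions: np.ndarray
    base_intensities: np.ndarray
    behavior_latents: dict[str, tuple[float, float]]  # sample_id -> (latency s, threshold g)
    config: CohortConfig


# behavioral latents by status: (latency mean s, latency spread s,
#                                threshold geometric mean g, log10 spread)
_CONTROL_LATENTS = (14.0, 1.5, 1.3, 0.06)
_MODEL_LATENTS = (8.5, 1.5, 0.55, 0.10)


def peak_fwhm(mz) -> np.ndarray:
    """Simulated peak width (FWHM, Da) at a given m/z: TOF-like, growing
    linearly with mass."""
    return 5.0 + 0.002 * np.asarray(mz, float)


_fwhm = peak_fwhm


def _render_spectrum(grid: np.ndarray, positions: np.ndarray,
                     heights: np.ndarray) -> np.ndarray:
    out = np.zeros_like(grid)
    sigma = _fwhm(positions) / 2.3548200450309493  # FWHM -> Gaussian sigma
    for p, h, s in zip(positions, heights, sigma):
        lo = np.searchsorted(grid, p - 5 * s)
        hi = np.searchsorted(grid, p + 5 * s)
        if hi > lo:
            out[lo:hi] += h * np.exp(-0.5 * ((grid[lo:hi] - p) / s) ** 2)
    return out


def generate_cohort(config: CohortConfig):
    """Simulate a full cohort.

    Returns
    -------
    spectra : list of Spectrum
        ``len(groups) * n_per_group * n_replicates`` sample acquisitions.
    blanks : list of Spectrum
        Matrix-blank acquisitions.
    behavior : list of BehaviorRecord
        One record per sample with derived outcomes filled in.
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mass_range
    grid = np.arange(lo, hi + config.grid_step / 2, config.grid_step)

    # --- peak library ------------------------------------------------------
    n_lib = config.peak_library_size
    n_info = max(1, round(config.informative_fraction * n_lib))
    n_low = round(config.low_mass_fraction * n_info)
    low_hi = min(1000.0, hi)
    pos_margin = 50.0
    info_low = rng.uniform(lo + pos_margin, low_hi, size=n_low)
    info_high = rng.uniform(low_hi, hi - pos_margin, size=n_info - n_low)
    info_pos = np.sort(np.concatenate([info_low, info_high]))
    rest = rng.uniform(lo + pos_margin, hi - pos_margin, size=n_lib - n_info)
    positions = np.concatenate([info_pos, rest])
    info_mask = np.zeros(n_lib, bool)
    info_mask[:n_info] = True
    order = np.argsort(positions)
    positions, info_mask = positions[order], info_mask[order]

    # base peak heights: log-normal, brighter at low mass as in serum spectra
    base = np.exp(rng.normal(np.log(30.0), 0.7, size=n_lib))
    base *= 1.0 + 1.5 * np.exp(-positions / 2000.0)

    # per-class multiplicative log-normal effect on informative peaks;
    # effect_size is the geometric SD, so effect_size == 1 gives exactly 1
    log_es = np.log(config.effect_size)
    class_mult = {}
    for g in config.groups:
        m = np.ones(n_lib)
        m[info_mask] = np.exp(rng.normal(0.0, 1.0, size=n_info) * log_es)
        class_mult[g] = m

    matrix_pos = np.sort(rng.uniform(lo + pos_margin, min(700.0, hi), config.n_matrix_peaks))
    matrix_heights = np.exp(rng.normal(np.log(40.0), 0.5, size=config.n_matrix_peaks))

    baseline = config.baseline_amplitude * np.exp(-grid / 1500.0)

    # --- samples -----------------------------------------------------------
    spectra: list[Spectrum] = []
    behavior: list[BehaviorRecord] = []
    labels: dict[str, str] = {}
    latents: dict[str, tuple[float, float]] = {}
    updown = UpDownParams()

    for g in config.groups:
        is_control = g.lower() in CONTROL_NAMES
        lat_mu, lat_sd, thr_gm, thr_sd = _CONTROL_LATENTS if is_control else _MODEL_LATENTS
        # small per-group behavioral offset keeps model groups overlapping
        group_lat = lat_mu + rng.normal(0.0, 0.5)
        group_thr = thr_gm * 10 ** rng.normal(0.0, 0.03)
        for i in range(config.n_per_group):
            sid = f"{g}_{i + 1:02d}"
            labels[sid] = g
            sample_factor = np.exp(rng.normal(0.0, config.biological_sigma, size=n_lib))
            heights = base * class_mult[g] * sample_factor
            for rep in range(1, config.n_replicates + 1):
                tech = np.exp(rng.normal(0.0, config.technical_sigma, size=n_lib))
                shift = rng.normal(0.0, config.mz_jitter_sd)
                signal = _render_spectrum(grid, positions + shift, heights * tech)
                signal += _render_spectrum(
                    grid, matrix_pos + shift,
                    matrix_heights * np.exp(rng.normal(0.0, config.technical_sigma,
                                                       size=config.n_matrix_peaks)))
                signal += baseline
                signal += rng.normal(0.0, config.noise_sd, size=grid.shape)
                np.clip(signal, 0.0, None, out=signal)
                spectra.append(Spectrum(grid.copy(), signal, sample_id=sid,
                                        replicate_id=rep, role="sample"))
            lat = max(1.0, group_lat + rng.normal(0.0, lat_sd))
            thr = float(np.clip(group_thr * 10 ** rng.normal(0.0, thr_sd),
                                updown.min_force, updown.max_force))
            latents[sid] = (lat, thr)
            behavior.append(generate_behavior(
                sid, lat, thr, rng, updown=updown))

    # --- matrix blanks -----------------------------------------------------
    blanks: list[Spectrum] = []
    for b in range(1, config.n_blanks + 1):
        shift = rng.normal(0.0, config.mz_jitter_sd)
        tech = np.exp(rng.normal(0.0, config.technical_sigma, size=config.n_matrix_peaks))
        signal = _render_spectrum(grid, matrix_pos + shift, matrix_heights * tech)
        signal += baseline
        signal += rng.normal(0.0, config.noise_sd, size=grid.shape)
        np.clip(signal, 0.0, None, out=signal)
        blanks.append(Spectrum(grid.copy(), signal, sample_id=f"blank_{b:02d}",
                               replicate_id=b, role="matrix_blank"))

    truth = GroundTruth(
        labels=labels,
        peak_positions=positions,
        informative_peak_positions=positions[info_mask],
        class_multipliers=class_mult,
        matrix_peak_positions=matrix_pos,
        base_intensities=base,
        behavior_latents=latents,
        config=config,
    )
    return spectra, blanks, behavior, truth


def generate_behavior(sample_id: str, latent_latency_s: float, latent_threshold_g: float,
                      seed: int | np.random.Generator,
                      n_trials: int = 3, trial_sd: float = 1.5,
                      psychometric_slope: float = 8.0,
                      updown: UpDownParams | None = None,
                      cutoff: float = 25.0) -> BehaviorRecord:
    """Simulate one animal's behavioral record from latent parameters.

    Latency trials are normal around the latent mean, censored at the
    cutoff; the von Frey sequence follows the up-down protocol under a
    logistic psychometric function of log filament force centred on the
    latent 50% threshold.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    updown = updown or UpDownParams()
    trials = rng.normal(latent_latency_s, trial_sd, size=n_trials)
    trials = np.clip(trials, 0.5, cutoff)
    seq = simulate_updown(latent_threshold_g, psychometric_slope, updown, rng)
    rec = BehaviorRecord(sample_id=sample_id,
                         latency_trials=[float(t) for t in trials],
                         vf_sequence=seq)
    return rec.derive(updown, cutoff)


def write_cohort(out_dir: str | Path, spectra, blanks, behavior, truth) -> CohortManifest:
    """Persist a cohort as per-spectrum delimited files + labels + manifest."""
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    samples: dict[str, dict] = {}
    for spec in spectra:
        fname = f"spectra/{spec.sample_id}_r{spec.replicate_id}.csv"
        write_spectrum(spec, out / fname)
        samples.setdefault(spec.sample_id,
                           {"label": truth.labels[spec.sample_id], "files": []})
        samples[spec.sample_id]["files"].append(fname)
    blank_files = []
    for spec in blanks:
        fname = f"spectra/{spec.sample_id}.csv"
        write_spectrum(spec, out / fname)
        blank_files.append(fname)
    manifest = CohortManifest(samples=samples, blank_files=blank_files,
                              label_set=sorted({r["label"] for r in samples.values()}))
    cfg = asdict(truth.config)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"samples": samples, "blank_files": blank_files,
                   "label_set": manifest.label_set, "config": cfg}, fh, indent=1)
    with open(out / "labels.csv", "w") as fh:
        fh.write("sample_id,label\n")
        for sid, rec in samples.items():
            fh.write(f"{sid},{rec['label']}\n")
    with open(out / "behavior.csv", "w") as fh:
        fh.write("sample_id,latency_trials,vf_sequence\n")
        for rec in behavior:
            lat = ";".join(f"{t:.3f}" for t in rec.latency_trials)
            seq = ";".join(f"{f}:{'X' if r else 'O'}" for f, r in rec.vf_sequence)
            fh.write(f"{rec.sample_id},{lat},{seq}\n")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "labels": truth.labels,
            "peak_positions": truth.peak_positions.tolist(),
            "informative_peak_positions": truth.informative_peak_positions.tolist(),
            "matrix_peak_positions": truth.matrix_peak_positions.tolist(),
            "behavior_latents": {k: list(v) for k, v in truth.behavior_latents.items()},
            "seed": truth.config.seed,
        }, fh, indent=1)
    return manifest
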