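"""Raw spectrum -> per-sample peak list.

The stages, in pipeline order: Savitzky-Golay smoothing, Loess (locally
weighted regression) baseline estimation and subtraction, normalization
of the base peak to 100%, rigid m/z alignment against a landmark
reference, local-maximum peak detection against a robust noise
estimate, majority-rule merging of plate replicates, and exclusion of
matrix peaks identified from blank acquisitions.  Each step appends one
entry to the spectrum's processing log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, savgol_filter
from statsmodels.nonparametric.smoothers_lowess import lowess

from .spectra import Spectrum

__all__ = [
    "PeakList", "PreprocessConfig", "ParameterError",
    "smooth_savgol", "subtract_baseline_loess", "normalize_max100",
    "align_spectra", "detect_peaks", "merge_replicates", "exclude_matrix_peaks",
    "preprocess_cohort",
]


class ParameterError(ValueError):
    """Invalid preprocessing parameter."""


class NormalizationError(ValueError):
    """Spectrum cannot be normalized (no signal)."""


@dataclass
class PeakList:
    """Discrete peaks for one spectrum or one merged replicate set.

    Intensities are relative (% of base peak, in [0, 100] after
    normalization of the parent spectrum).
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    n_replicates_merged: int = 1
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if len(self.mz) != len(self.intensity):
            raise ValueError("peak m/z and intensity length mismatch")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz)
            self.mz, self.intensity = self.mz[order], self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class PreprocessConfig:
    """Tunable preprocessing parameters.

    The source study names Savitzky-Golay and Loess but states no
    parameters; the defaults here (window of 9 grid points, quadratic
    polynomial, Loess span 0.1) are exposed so they can be revisited.
    """

    savgol_window: int = 9
    savgol_order: int = 2
    loess_span: float = 0.1
    align_tolerance: float = 3.0       # Da
    snr_threshold: float = 3.0
    blank_match_tolerance: float = 2.0  # Da
    blank_min_rel_intensity: float = 5.0  # %; blank peaks below this are noise, not matrix ions
    merge_tolerance: float = 3.0        # Da, replicate peak matching (> grid step)
    peak_measure: str = "apex"          # "apex" or "area"

    def validate(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_order >= self.savgol_window:
            raise ParameterError("savgol: window must be odd and > order")
        if not (0 < self.loess_span <= 1):
            raise ParameterError("loess_span must be in (0, 1]")
        if min(self.align_tolerance, self.snr_threshold,
               self.blank_match_tolerance, self.merge_tolerance) <= 0:
            raise ParameterError("tolerances must be positive")
        if self.peak_measure not in ("apex", "area"):
            raise ParameterError("peak_measure must be 'apex' or 'area'")


# ---------------------------------------------------------------------------

def smooth_savgol(spectrum: Spectrum, window: int = 9, order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing: local least-squares polynomial fit."""
    if window % 2 == 0:
        raise ParameterError(f"savgol window must be odd, got {window}")
    if order >= window:
        raise ParameterError(f"savgol order {order} must be < window {window}")
    if len(spectrum) < window:
        raise ParameterError(f"spectrum length {len(spectrum)} < window {window}")
    sm = savgol_filter(spectrum.intensity, window_length=window, polyorder=order)
    return spectrum.copy_with(intensity=sm, log_entry=f"savgol(window={window},order={order})")


def subtract_baseline_loess(spectrum: Spectrum, span: float = 0.1) -> Spectrum:
    """Estimate the baseline by Loess regression of intensity on m/z and
    subtract it; negative residuals are clipped to zero."""
    if not (0 < span <= 1):
        raise ParameterError(f"loess span must be in (0, 1], got {span}")
    if len(spectrum) < 10:
        raise ParameterError("need >= 10 points for baseline estimation")
    mz, inten = spectrum.mz, spectrum.intensity
    # asymmetric reweighting: peaks sit above the baseline, so fit the
    # loess to a running-minimum-like envelope before the final smooth
    base0 = median_filter(inten, size=max(3, len(inten) // 50), mode="nearest")
    envelope = np.minimum(inten, base0)
    delta = 0.01 * (mz[-1] - mz[0])
    fitted = lowess(envelope, mz, frac=span, it=2, delta=delta, return_sorted=False)
    residual = inten - fitted
    np.clip(residual, 0.0, None, out=residual)
    return spectrum.copy_with(intensity=residual, log_entry=f"loess_baseline(span={span})")


def normalize_max100(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the base peak equals exactly 100%."""
    peak = float(np.max(spectrum.intensity))
    if peak <= 0:
        raise NormalizationError("all-zero spectrum cannot be normalized")
    return spectrum.copy_with(intensity=spectrum.intensity * (100.0 / peak),
                              log_entry="normalize_max100")


def _landmarks(spectrum: Spectrum, top: int = 40) -> np.ndarray:
    """m/z of the most prominent local maxima, used for alignment."""
    height = max(1.0, 0.02 * float(np.max(spectrum.intensity)))
    idx, props = find_peaks(spectrum.intensity, height=height, prominence=height)
    if len(idx) > top:
        keep = np.argsort(props["prominences"])[-top:]
        idx = np.sort(idx[keep])
    return spectrum.mz[idx]


def _match_count(a: np.ndarray, b: np.ndarray, tol: float) -> int:
    if len(a) == 0 or len(b) == 0:
        return 0
    j = np.searchsorted(b, a)
    j = np.clip(j, 1, len(b) - 1)
    nearest = np.minimum(np.abs(b[j] - a), np.abs(b[j - 1] - a))
    return int(np.sum(nearest <= tol))


def align_spectra(spectra: list[Spectrum], tolerance: float = 3.0) -> list[Spectrum]:
    """Rigidly shift each spectrum in m/z to best match a landmark reference.

    The reference is the spectrum with the most detected landmark peaks.
    Candidate shifts are grid multiples within +/- tolerance; the shift
    maximizing matched landmarks (ties -> smallest |shift|) is applied.
    A spectrum with no matching landmarks keeps the identity shift with
    a warning.
    """
    if len(spectra) < 2:
        return [s.copy_with(log_entry="align(shift=0.0)") for s in spectra]
    if tolerance <= 0:
        raise ParameterError("align tolerance must be positive")
    marks = [_landmarks(s) for s in spectra]
    ref_i = int(np.argmax([len(m) for m in marks]))
    ref = marks[ref_i]
    match_tol = 1.5  # Da; landmark coincidence window
    out = []
    for s, m in zip(spectra, marks):
        step = float(np.median(np.diff(s.mz)))
        n_steps = max(1, int(round(tolerance / step)))
        shifts = np.arange(-n_steps, n_steps + 1) * step
        best_shift, best_score = 0.0, -1
        for sh in shifts[np.argsort(np.abs(shifts), kind="stable")]:
            score = _match_count(m + sh, ref, match_tol)
            if score > best_score:
                best_shift, best_score = float(sh), score
        if best_score == 0:
            warnings.warn(f"{s.sample_id} r{s.replicate_id}: no landmarks matched; "
                          "identity shift applied", stacklevel=2)
            best_shift = 0.0
        out.append(s.copy_with(mz=s.mz + best_shift,
                               log_entry=f"align(shift={best_shift:+.3f})"))
    return out


def detect_peaks(spectrum: Spectrum, snr_threshold: float = 3.0,
                 measure: str = "apex") -> PeakList:
    """Local maxima exceeding ``snr_threshold`` times a robust noise level.

    Noise is estimated robustly from the median-detrended signal: the
    larger of 1.4826 x its median absolute deviation and its 84.1th
    percentile (the one-sigma point of the upper tail, which stays valid
    after zero-clipping has removed the lower noise tail).  Peak
    intensity is the apex height by default (``measure="area"``
    integrates a window of one FWHM-scale neighbourhood instead).
    """
    inten = spectrum.intensity
    detrended = inten - median_filter(inten, size=max(3, min(51, len(inten) // 10 * 2 + 1)),
                                      mode="nearest")
    mad = float(np.median(np.abs(detrended - np.median(detrended))))
    sigma = max(1.4826 * mad, float(np.percentile(detrended, 84.1)))
    if sigma <= 0:
        sigma = float(np.std(detrended)) or 1e-12
    height = snr_threshold * sigma
    idx, _ = find_peaks(inten, height=height, prominence=height / 2)
    if measure == "area":
        vals = np.array([float(np.trapezoid(inten[max(0, i - 3):i + 4],
                                            spectrum.mz[max(0, i - 3):i + 4]))
                         for i in idx])
    else:
        vals = inten[idx]
    return PeakList(mz=spectrum.mz[idx], intensity=vals,
                    sample_id=spectrum.sample_id,
                    log=list(spectrum.processing_log) + [f"detect_peaks(snr={snr_threshold})"])


def merge_replicates(peaklists: list[PeakList], tolerance: float = 2.0) -> PeakList:
    """Merge plate-replicate peak lists by greedy m/z matching.

    Peaks within `tolerance` across replicates are pooled into one peak
    (m/z and intensity averaged over the replicates that show it); peaks
    present in fewer than half of the replicates are dropped.
    """
    if not peaklists:
        raise ValueError("no peak lists to merge")
    sids = {p.sample_id for p in peaklists}
    if len(sids) != 1:
        raise ValueError(f"mixed sample_ids in replicate merge: {sorted(sids)}")
    n_rep = len(peaklists)
    pooled = np.concatenate([p.mz for p in peaklists])
    inten = np.concatenate([p.intensity for p in peaklists])
    rep_of = np.concatenate([np.full(len(p), k) for k, p in enumerate(peaklists)])
    if len(pooled) == 0:
        return PeakList(pooled, inten, sample_id=peaklists[0].sample_id,
                        n_replicates_merged=n_rep)
    order = np.argsort(pooled, kind="stable")
    pooled, inten, rep_of = pooled[order], inten[order], rep_of[order]
    # greedy 1-D clustering: break where the gap to the previous peak > tolerance
    breaks = np.nonzero(np.diff(pooled) > tolerance)[0] + 1
    groups = np.split(np.arange(len(pooled)), breaks)
    mzs, vals = [], []
    majority = n_rep / 2.0
    for g in groups:
        reps = np.unique(rep_of[g])
        if len(reps) < majority:
            continue
        # average one value per replicate (a replicate may contribute 2 close peaks)
        per_rep = [float(np.mean(inten[g][rep_of[g] == r])) for r in reps]
        mzs.append(float(np.mean(pooled[g])))
        vals.append(float(np.mean(per_rep)))
    return PeakList(np.asarray(mzs), np.asarray(vals),
                    sample_id=peaklists[0].sample_id, n_replicates_merged=n_rep,
                    log=[f"merge_replicates(n={n_rep},tol={tolerance})"])


def exclude_matrix_peaks(peaklist: PeakList, blank_peaklists: list[PeakList],
                         tolerance: float = 2.0) -> PeakList:
    """Remove sample peaks within `tolerance` of any blank (matrix) peak."""
    if not blank_peaklists:
        warnings.warn("no blank peak lists given; matrix exclusion skipped", stacklevel=2)
        return peaklist
    blanks = np.sort(np.concatenate([b.mz for b in blank_peaklists]))
    if len(blanks) == 0 or len(peaklist) == 0:
        keep = np.ones(len(peaklist), bool)
    else:
        j = np.clip(np.searchsorted(blanks, peaklist.mz), 1, len(blanks) - 1)
        nearest = np.minimum(np.abs(blanks[j] - peaklist.mz),
                             np.abs(blanks[j - 1] - peaklist.mz))
        keep = nearest > tolerance
    removed = int(np.sum(~keep))
    return PeakList(peaklist.mz[keep], peaklist.intensity[keep],
                    sample_id=peaklist.sample_id,
                    n_replicates_merged=peaklist.n_replicates_merged,
                    log=peaklist.log + [f"exclude_matrix(removed={removed},tol={tolerance})"])


# ---------------------------------------------------------------------------

def preprocess_cohort(spectra: list[Spectrum], blanks: list[Spectrum],
                      config: PreprocessConfig | None = None
                      ) -> tuple[dict[str, PeakList], list[PeakList]]:
    """Run the full per-spectrum chain and replicate merge for a cohort.

    Samples and blanks go through the identical smooth -> baseline ->
    normalize -> align -> detect chain (aligned together, so matrix
    landmarks shared by both anchor the shift); sample replicates are
    then merged per sample and matrix peaks from the blanks excluded.

    Returns a mapping sample_id -> final PeakList, plus the blank peak
    lists.
    """
    config = config or PreprocessConfig()
    config.validate()
    everything = list(spectra) + list(blanks)
    stage = [normalize_max100(
        subtract_baseline_loess(
            smooth_savgol(s, config.savgol_window, config.savgol_order),
            config.loess_span))
        for s in everything]
    stage = align_spectra(stage, config.align_tolerance)
    peaklists = [detect_peaks(s, config.snr_threshold, config.peak_measure) for s in stage]
    sample_pls: dict[str, list[PeakList]] = {}
    blank_pls: list[PeakList] = []
    for s, pl in zip(stage, peaklists):
        if s.role == "matrix_blank":
            blank_pls.append(pl)
        else:
            sample_pls.setdefault(s.sample_id, []).append(pl)
    merged = {sid: merge_replicates(pls, config.merge_tolerance)
              for sid, pls in sample_pls.items()}
    if blank_pls:
        # only strong blank peaks are matrix ions; weak local maxima in a
        # blank are noise and must not open exclusion windows
        strong = [PeakList(b.mz[b.intensity >= config.blank_min_rel_intensity],
                           b.intensity[b.intensity >= config.blank_min_rel_intensity],
                           sample_id=b.sample_id) for b in blank_pls]
        merged = {sid: exclude_matrix_peaks(pl, strong, config.blank_match_tolerance)
                  for sid, pl in merged.items()}
    return merged, blank_pls
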