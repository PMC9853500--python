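"""Reflexive-pain outcome variables.

Two behavioral readouts are fused into the spectral classifier:

* **Thermal hyperalgesia (PTD)** — mean paw-withdrawal latency to
  radiant heat (Hargreaves plantar test), in seconds, capped at a 25 s
  cutoff, averaged over at least three trials.

* **Mechanical allodynia (VFD)** — the 50% paw-withdrawal force
  threshold to von Frey filaments (bending forces 0.04–2 g), measured
  with the adaptive up-down staircase and converted to grams with the
  Dixon formula::

      threshold_g = 10 ** (Xf + kappa * delta) / 10_000

  where ``Xf = log10(10_000 * final_force_g)`` is the final filament in
  log units, ``delta`` is the mean log10 spacing of the filament set,
  and ``kappa`` is a tabulated correction determined by the pattern of
  positive/negative responses.  The shipped kappa table
  (``data/kappa_table_computed.csv``) is computed by maximum likelihood
  under the classical normal-ogive staircase model (response probability
  a normal CDF in log-force with scale ``delta``); it is keyed by the
  full response pattern and is user-replaceable.

Protocol conventions: testing starts at the 0.4 g filament, steps one
filament down after a response and one up after a non-response, and
stops four measurements after the first response.  An animal that never
responds through the top filament is reported at 2 g; thresholds are
clamped to the filament range.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "BehaviorRecord",
    "UpDownParams",
    "ProtocolError",
    "DEFAULT_FILAMENTS",
    "mean_withdrawal_latency",
    "updown_50pct_threshold",
    "simulate_updown",
    "kappa_from_pattern_ml",
]

#: Standard mouse von Frey filament set (bending force, g).
DEFAULT_FILAMENTS: tuple[float, ...] = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0)

LATENCY_CUTOFF_S = 25.0
MIN_LATENCY_TRIALS = 3

# MLE bound on (mu - x_final) in delta units; keeps degenerate all-response
# patterns finite, mirroring the bounded range of the classical tables.
_KAPPA_BOUND = 2.0


class ProtocolError(ValueError):
    """An up-down sequence that violates the staircase transition rules."""


@dataclass
class UpDownParams:
    """Configuration of the up-down staircase and Dixon estimator.

    ``delta`` defaults to the mean log10 spacing of ``filament_set`` and
    is recomputed from it rather than hard-coded.
    """

    filament_set: tuple[float, ...] = DEFAULT_FILAMENTS
    start_force: float = 0.4
    stop_after_first_response: int = 4
    kappa_table: dict[str, float] | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        fs = tuple(float(f) for f in self.filament_set)
        if any(b <= a for a, b in zip(fs, fs[1:])):
            raise ValueError("filament_set must be strictly increasing")
        if self.start_force not in fs:
            raise ValueError(f"start_force {self.start_force} not in filament_set")
        self.filament_set = fs
        if self.delta is None:
            logs = np.log10(np.asarray(fs))
            self.delta = float(np.mean(np.diff(logs)))
        if self.kappa_table is None:
            self.kappa_table = _load_packaged_kappa_table()

    @property
    def min_force(self) -> float:
        return self.filament_set[0]

    @property
    def max_force(self) -> float:
        return self.filament_set[-1]


@dataclass
class BehaviorRecord:
    """Per-animal behavioral data plus the two derived outcome variables."""

    sample_id: str
    latency_trials: list[float] = field(default_factory=list)
    vf_sequence: list[tuple[float, bool]] = field(default_factory=list)
    derived_latency_mean: float | None = None
    derived_threshold_50: float | None = None

    def derive(self, params: UpDownParams | None = None,
               cutoff: float = LATENCY_CUTOFF_S) -> "BehaviorRecord":
        """Fill the derived fields from the raw trials/sequence."""
        params = params or UpDownParams()
        if self.latency_trials:
            self.derived_latency_mean = mean_withdrawal_latency(self.latency_trials, cutoff)
        if self.vf_sequence:
            self.derived_threshold_50 = updown_50pct_threshold(self.vf_sequence, params)
        return self


def mean_withdrawal_latency(trials, cutoff: float = LATENCY_CUTOFF_S) -> float:
    """Mean thermal withdrawal latency with cutoff capping.

    Trials longer than `cutoff` (imposed to avoid skin damage) are
    recorded as the cutoff itself before averaging.
    """
    trials = [float(t) for t in trials]
    if len(trials) < MIN_LATENCY_TRIALS:
        raise ValueError(f"need at least {MIN_LATENCY_TRIALS} latency trials, got {len(trials)}")
    if any(t <= 0 for t in trials):
        raise ValueError("latency trials must be positive")
    return float(np.mean(np.minimum(trials, cutoff)))


# ---------------------------------------------------------------------------
# kappa table

def _pattern(sequence) -> str:
    return "".join("X" if bool(r) else "O" for _, r in sequence)


def kappa_from_pattern_ml(pattern: str, start_offset: int = 0) -> float:
    """Maximum-likelihood kappa for a response pattern.

    The staircase is modelled on an integer grid in delta units: the
    probability of a response at level x is ``Phi(x - mu)`` with unit
    (= delta) scale.  The forces implied by the pattern are reconstructed
    relative to the final level, mu is estimated by ML bounded to within
    ``+/-2`` delta of the final level, and kappa = mu_hat - x_final.

    `start_offset` shifts the starting level (used only to clamp the
    reconstructed staircase at range boundaries when enumerating the
    packaged table; the default assumes no boundary contact).
    """
    if not pattern or any(c not in "OX" for c in pattern):
        raise ValueError(f"invalid pattern {pattern!r}")
    levels = [0]
    for c in pattern[:-1]:
        levels.append(levels[-1] + (1 if c == "O" else -1))
    levels = np.asarray(levels, float) + start_offset
    x_final = levels[-1]
    responses = np.array([c == "X" for c in pattern])

    def nll(mu: float) -> float:
        z = levels - mu
        logp = norm.logcdf(z)
        log1mp = norm.logcdf(-z)
        return -float(np.sum(np.where(responses, logp, log1mp)))

    res = minimize_scalar(nll, bounds=(x_final - _KAPPA_BOUND, x_final + _KAPPA_BOUND),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x - x_final)


@functools.lru_cache(maxsize=1)
def _load_packaged_kappa_table() -> dict[str, float]:
    path = resources.files("painprint").joinpath("data/kappa_table_computed.csv")
    table: dict[str, float] = {}
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["pattern"]] = float(row["kappa"])
    return dict(table)


# ---------------------------------------------------------------------------
# Dixon estimator

def _step_index(force: float, params: UpDownParams) -> int:
    fs = np.asarray(params.filament_set)
    i = int(np.argmin(np.abs(fs - force)))
    if abs(fs[i] - force) > 1e-9:
        raise ProtocolError(f"force {force} g is not in the filament set")
    return i


def _validate_sequence(sequence, params: UpDownParams) -> None:
    if not sequence:
        raise ProtocolError("empty sequence")
    n_fil = len(params.filament_set)
    idx = _step_index(sequence[0][0], params)
    if abs(sequence[0][0] - params.start_force) > 1e-9:
        raise ProtocolError(
            f"step 1: sequence starts at {sequence[0][0]} g, protocol starts at "
            f"{params.start_force} g")
    first_resp = None
    for k, (force, resp) in enumerate(sequence):
        j = _step_index(force, params)
        if j != idx:
            raise ProtocolError(f"step {k + 1}: expected filament "
                                f"{params.filament_set[idx]} g, got {force} g")
        if first_resp is None and resp:
            first_resp = k
        idx = min(j + 1, n_fil - 1) if not resp else max(j - 1, 0)
    # termination rule
    last_force, last_resp = sequence[-1]
    if first_resp is None:
        if _step_index(last_force, params) != n_fil - 1 or last_resp:
            raise ProtocolError("no-response sequence must terminate at the top filament")
    else:
        expected_len = first_resp + 1 + params.stop_after_first_response
        if len(sequence) != expected_len:
            raise ProtocolError(
                f"sequence has {len(sequence)} measurements; protocol stops "
                f"{params.stop_after_first_response} after the first response "
                f"(expected {expected_len})")


def updown_50pct_threshold(sequence, params: UpDownParams | None = None) -> float:
    """50% paw-withdrawal threshold (g) from an up-down sequence.

    Applies the Dixon formula ``10**(Xf + kappa*delta) / 10_000`` with
    ``Xf = log10(10_000 * final_force_g)``; the result is clamped to the
    filament range.  Boundary rules: an animal with no response through
    the top filament is reported at the top force; one that responds at
    the bottom repeatedly cannot fall below the bottom force.
    """
    params = params or UpDownParams()
    sequence = [(float(f), bool(r)) for f, r in sequence]
    _validate_sequence(sequence, params)
    pattern = _pattern(sequence)
    if "X" not in pattern:
        return params.max_force
    final_force = sequence[-1][0]
    table = params.kappa_table
    if pattern in table:
        kappa = table[pattern]
    else:  # custom protocol lengths: fall back to the same ML model
        kappa = kappa_from_pattern_ml(pattern)
    xf = np.log10(10_000.0 * final_force)
    thr = 10.0 ** (xf + kappa * params.delta) / 10_000.0
    return float(np.clip(thr, params.min_force, params.max_force))


def simulate_updown(latent_threshold: float, slope: float,
                    params: UpDownParams | None = None,
                    seed: int | np.random.Generator = 0) -> list[tuple[float, bool]]:
    """Simulate a protocol-valid up-down sequence.

    The animal responds to force F with probability
    ``1 / (1 + exp(-slope * log10(F / latent_threshold)))`` — a logistic
    psychometric function of log force centred on the latent 50%
    threshold (`slope` in units of 1/log10-g; ``numpy.inf`` gives a
    deterministic step function).
    """
    if latent_threshold <= 0:
        raise ValueError("latent_threshold must be positive")
    params = params or UpDownParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = params.filament_set
    idx = _step_index(params.start_force, params)
    seq: list[tuple[float, bool]] = []
    after_first = None
    while True:
        force = fs[idx]
        lx = np.log10(force / latent_threshold)
        if np.isinf(slope):
            p = 1.0 if lx >= 0 else 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-slope * lx))
        resp = bool(rng.random() < p)
        seq.append((force, resp))
        if after_first is None and resp:
            after_first = 0
        elif after_first is not None:
            after_first += 1
        if after_first is not None and after_first >= params.stop_after_first_response:
            break
        if after_first is None and not resp and idx == len(fs) - 1:
            break  # never responded through the top filament
        idx = max(idx - 1, 0) if resp else min(idx + 1, len(fs) - 1)
    return seq
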