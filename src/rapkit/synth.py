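"""Synthetic signal and cohort generation.

Every downstream stage of the pipeline (index derivation, ARIMA structure
analysis, artifact detection) is exercised against data from this module,
which emulates the relevant features of bedside neuromonitoring archives:

* pulsatile ICP/ABP waveforms with cardiac and respiratory components, a
  slow random-walk trend, and a tunable coupling between the slow ICP level
  and the cardiac pulse amplitude.  Positive coupling makes slow ICP and
  pulse amplitude co-move, which is exactly the regime the RAP index
  measures (high RAP = impaired compensatory reserve); zero coupling
  decouples them (RAP near zero).
* ARMA/ARIMA series of known (p, d, q) with known coefficients, used as
  ground truth for order-recovery studies.
* labeled artifact injection (spike trains, flatlines, steps, noise bursts,
  dropouts) with an exact ground-truth mask.
* synthetic patient cohorts with admission covariates, for subgroup tests.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from statsmodels.tsa.arima_process import arma_generate_sample

from .core import ArtifactMask, IndexSeries, InvalidParameterError, PhysioRecording

ARTIFACT_KINDS = ("spike", "flatline", "step", "noise_burst", "dropout")

# Fixed respiratory amplitudes (mmHg) for the two channels; small relative to
# the cardiac pulse so the spectral estimate of the fundamental is clean.
_RESP_AMP_ICP = 0.5
_RESP_AMP_ABP = 2.0
_ABP_PULSE_AMP = 40.0  # systolic-diastolic half-swing of the synthetic ABP


@dataclass
class WaveformParams:
    """Parameters of the pulsatile waveform generator.

    ``coupling`` in [-1, 1] sets the strength and sign of the relationship
    between the standardized slow ICP trend z(t) and the cardiac pulse
    amplitude: amplitude(t) = pulse_amplitude * exp(coupling * z(t) +
    amp_jitter * eta(t)), where eta is an independent smooth unit-variance
    process emulating beat-to-beat amplitude variability.  The exponential
    keeps the amplitude strictly positive at any coupling while preserving
    monotonicity in z, and the jitter term grades the within-window ICP-AMP
    correlation smoothly with |coupling| instead of saturating at 1.
    """

    duration: float = 7200.0        # seconds
    sample_rate: float = 100.0      # Hz
    heart_rate: float = 70.0        # beats/min
    resp_rate: float = 16.0         # breaths/min
    icp_baseline: float = 15.0      # mmHg
    abp_baseline: float = 90.0      # mmHg
    pulse_amplitude: float = 2.0    # mmHg
    coupling: float = 0.0           # unitless, [-1, 1]
    trend_sd: float = 0.2           # mmHg per 10-s random-walk step
    noise_sd: float = 0.3           # mmHg per-sample white noise
    amp_jitter: float = 0.1         # log-scale SD of beat-amplitude variability
    seed: int = 0

    def validate(self, pulsatile: bool = True) -> None:
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if pulsatile and self.sample_rate < 50:
            raise InvalidParameterError("pulsatile output requires sample_rate >= 50 Hz")
        if not 40 <= self.heart_rate <= 180:
            raise InvalidParameterError("heart_rate must be within [40, 180] beats/min")
        if not -1 <= self.coupling <= 1:
            raise InvalidParameterError("coupling must lie in [-1, 1]")
        if self.trend_sd < 0 or self.noise_sd < 0 or self.amp_jitter < 0:
            raise InvalidParameterError("trend_sd, noise_sd and amp_jitter must be non-negative")


def _slow_trend(n: int, sample_rate: float, step_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk trend with N(0, step_sd) increments every 10 s, linearly
    interpolated onto the sample grid.  Returns zeros when step_sd == 0."""
    if step_sd == 0 or n == 0:
        return np.zeros(n)
    step = max(int(round(10 * sample_rate)), 1)
    n_knots = n // step + 2
    knots = np.concatenate(([0.0], np.cumsum(rng.normal(0.0, step_sd, n_knots - 1))))
    t = np.arange(n) / step
    return np.interp(t, np.arange(n_knots), knots)


def simulate_pulsatile(params: WaveformParams) -> PhysioRecording:
    """Generate synthetic pulsatile ICP and ABP channels.

    The ICP channel is baseline + slow trend + respiratory oscillation +
    amplitude-modulated cardiac pulse + white noise.  The cardiac pulse is a
    fundamental plus a weaker second harmonic; only the fundamental's
    amplitude is modulated and only the fundamental is what the AMP
    derivation measures, so no attempt is made at realistic P1/P2/P3
    morphology.
    """
    params.validate(pulsatile=True)
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    slow_icp = _slow_trend(n, params.sample_rate, params.trend_sd, rng)
    sd = slow_icp.std()
    z = (slow_icp - slow_icp.mean()) / sd if sd > 0 else np.zeros(n)
    if params.amp_jitter > 0:
        # beat-amplitude variability: white N(0,1) knots every 10 s,
        # linearly interpolated (smooth, but decorrelated across the
        # 5-min correlation window)
        step = max(int(round(10 * params.sample_rate)), 1)
        n_knots = n // step + 2
        eta = np.interp(np.arange(n) / step, np.arange(n_knots), rng.standard_normal(n_knots))
    else:
        eta = np.zeros(n)
    amp = params.pulse_amplitude * np.exp(params.coupling * z + params.amp_jitter * eta)

    f_card = params.heart_rate / 60.0
    f_resp = params.resp_rate / 60.0
    cardiac = np.sin(2 * np.pi * f_card * t) + 0.3 * np.sin(4 * np.pi * f_card * t)
    resp = np.sin(2 * np.pi * f_resp * t) if params.resp_rate > 0 else np.zeros(n)

    icp = (
        params.icp_baseline
        + slow_icp
        + _RESP_AMP_ICP * resp
        + amp * np.sin(2 * np.pi * f_card * t)
        + 0.3 * amp * np.sin(4 * np.pi * f_card * t)
        + (rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0)
    )

    slow_abp = _slow_trend(n, params.sample_rate, 2 * params.trend_sd, rng)
    abp = (
        params.abp_baseline
        + slow_abp
        + _RESP_AMP_ABP * resp
        + _ABP_PULSE_AMP / 2 * cardiac
        + (rng.normal(0.0, 2 * params.noise_sd, n) if params.noise_sd > 0 else 0.0)
    )

    return PhysioRecording(
        time=t, channels={"ICP": icp, "ABP": abp}, sample_rate=params.sample_rate
    )


def simulate_arma(
    spec,
    ar_coeffs: Sequence[float] = (),
    ma_coeffs: Sequence[float] = (),
    n: int = 1000,
    innovation_sd: float = 1.0,
    const: float = 0.0,
    seed: int = 0,
    resolution: str = "1min",
    name: str = "synthetic",
) -> IndexSeries:
    """Simulate X_t = c + eps_t + sum_i phi_i X_{t-i} + sum_j theta_j eps_{t-j}.

    ``spec`` is an :class:`~rapkit.arima.ArimaSpec` (or any object with
    p/d/q attributes); ``ar_coeffs`` are phi_1..phi_p and ``ma_coeffs`` are
    theta_1..theta_q.  With d = 1 the cumulative sum of the ARMA process is
    returned (an integrated series).  Gaussian innovations; deterministic
    given the seed.
    """
    ar = np.asarray(ar_coeffs, dtype=float)
    ma = np.asarray(ma_coeffs, dtype=float)
    if len(ar) != spec.p or len(ma) != spec.q:
        raise InvalidParameterError("coefficient lengths must match spec orders p and q")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    ar_poly = np.r_[1.0, -ar]
    ma_poly = np.r_[1.0, ma]
    # stationarity/invertibility: all roots of the lag polynomials must lie
    # outside the unit circle (np.roots wants descending powers, hence [::-1])
    if spec.p > 0:
        roots = np.roots(ar_poly[::-1])
        if np.any(np.abs(roots) <= 1.0 + 1e-9):
            raise InvalidParameterError("AR polynomial is explosive or borderline non-stationary")
    if spec.q > 0:
        roots = np.roots(ma_poly[::-1])
        if np.any(np.abs(roots) <= 1.0 + 1e-9):
            raise InvalidParameterError("MA polynomial is non-invertible")

    rng = np.random.default_rng(seed)
    # burn-in long enough for slowly mixing (near-unit-root) AR components
    burnin = 2000 + 10 * (spec.p + spec.q)
    x = arma_generate_sample(
        ar_poly, ma_poly, n, scale=innovation_sd, distrvs=rng.standard_normal, burnin=burnin
    )
    if const != 0.0:
        x = x + const / (1.0 - ar.sum())
    if spec.d == 1:
        x = np.cumsum(x)
    elif spec.d != 0:
        raise InvalidParameterError("only d in {0, 1} is supported")

    from .core import RESOLUTION_SECONDS

    step = RESOLUTION_SECONDS[resolution]
    return IndexSeries(name=name, time=step * np.arange(1, n + 1), values=x, resolution=resolution)


@dataclass
class ArtifactSpec:
    """Description of the artifact process to inject.

    ``rate`` is events per hour; event count over a recording is Poisson.
    ``magnitude_range`` is in multiples of the clean signal's standard
    deviation, so the same spec scales across channels.
    """

    kinds: tuple[str, ...] = ARTIFACT_KINDS
    rate: float = 4.0                       # events / hour
    duration_range: tuple[float, float] = (10.0, 60.0)   # seconds
    magnitude_range: tuple[float, float] = (4.0, 10.0)   # multiples of the amplitude reference
    scale_mode: str = "auto"                # amplitude reference, see below
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidParameterError("rate must be >= 0")
        lo, hi = self.duration_range
        if lo <= 0 or hi < lo:
            raise InvalidParameterError("duration_range must be positive and ordered")
        for k in self.kinds:
            if k not in ARTIFACT_KINDS:
                raise InvalidParameterError(f"unknown artifact kind {k!r}")
        if self.scale_mode not in ("auto", "sd", "increment_sd"):
            raise InvalidParameterError("scale_mode must be auto/sd/increment_sd")


def _apply_event(values: np.ndarray, start: int, stop: int, kind: str,
                 magnitude: float, scale: float, rng: np.random.Generator) -> None:
    seg = slice(start, stop)
    width = stop - start
    if kind == "spike":
        # A short train of sharp alternating deflections (flush/ringing
        # morphology) rather than one isolated sample: every 5th sample.
        idx = np.arange(start, stop, 5)
        signs = np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
        values[idx] += signs * magnitude * scale
    elif kind == "flatline":
        values[seg] = values[start]
    elif kind == "step":
        values[seg] += magnitude * scale
    elif kind == "noise_burst":
        values[seg] += rng.normal(0.0, magnitude * scale, width)
    elif kind == "dropout":
        values[seg] = 0.0


def _amplitude_scale(values: np.ndarray, mode: str) -> float:
    """Amplitude reference for artifact magnitudes.

    For stationary pulsatile waveforms the per-sample SD is the natural
    scale; for trend-dominated (integrated) index series the per-sample SD
    grows with recording length, so the SD of first differences — the
    local fluctuation scale — is used instead.
    """
    if mode == "increment_sd" and values.size >= 2:
        s = float(np.std(np.diff(values)))
    else:
        s = float(np.std(values))
    return s if s > 0 else 1.0


def _inject(values_by_channel: dict[str, np.ndarray], time: np.ndarray,
            spec: ArtifactSpec, default_scale_mode: str = "sd") -> np.ndarray:
    """Corrupt channels in place with a shared event schedule; return mask."""
    n = time.size
    mask = np.zeros(n, dtype=bool)
    if spec.rate == 0 or n == 0:
        return mask
    rng = np.random.default_rng(spec.seed)
    duration_s = time[-1] - time[0] if n > 1 else 0.0
    dt = duration_s / (n - 1) if n > 1 else 1.0
    n_events = rng.poisson(spec.rate * duration_s / 3600.0)
    mode = default_scale_mode if spec.scale_mode == "auto" else spec.scale_mode
    scales = {k: _amplitude_scale(v, mode) for k, v in values_by_channel.items()}
    for _ in range(n_events):
        kind = spec.kinds[rng.integers(len(spec.kinds))]
        dur = rng.uniform(*spec.duration_range)
        width = max(int(round(dur / dt)), 1)
        start = int(rng.integers(0, max(n - width, 1)))
        stop = min(start + width, n)
        magnitude = rng.uniform(*spec.magnitude_range)
        for name, values in values_by_channel.items():
            _apply_event(values, start, stop, kind, magnitude, scales[name], rng)
        mask[start:stop] = True
    return mask


def inject_artifacts(recording: PhysioRecording, spec: ArtifactSpec) -> tuple[PhysioRecording, ArtifactMask]:
    """Return a corrupted copy of ``recording`` plus the ground-truth mask.

    All channels share the same event schedule (artifact events at the
    bedside — line flushes, transducer handling — typically hit the whole
    export).  Untouched samples are bit-identical to the input; a zero-rate
    spec returns an identical copy with an all-false mask.
    """
    if len(recording) == 0:
        raise InvalidParameterError("recording is empty")
    out = recording.copy()
    mask = _inject(out.channels, out.time, spec, default_scale_mode="sd")
    return out, ArtifactMask(time=out.time, flags=mask, provenance="ground_truth")


def inject_artifacts_series(series: IndexSeries, spec: ArtifactSpec) -> tuple[IndexSeries, ArtifactMask]:
    """Artifact injection for a derived index series (same event model)."""
    if len(series) == 0:
        raise InvalidParameterError("series is empty")
    out = series.copy()
    mask = _inject({series.name: out.values}, out.time, spec, default_scale_mode="increment_sd")
    return out, ArtifactMask(time=out.time, flags=mask, provenance="ground_truth")


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class Patient:
    identifier: str
    recording: PhysioRecording
    covariates: dict
    mask: ArtifactMask


@dataclass
class SyntheticCohort:
    patients: list[Patient] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


#: coupling level by Marshall CT grade: worsening diffuse injury (II -> IV)
#: raises the ICP-AMP coupling; grade V (evacuated mass lesion) sits between
#: III and IV, mirroring the non-monotone pattern reported for that grade.
_COUPLING_BY_MARSHALL = {"II": 0.15, "III": 0.45, "IV": 0.75, "V": 0.6}


def sample_covariates(rng: np.random.Generator) -> dict:
    """Admission covariates with distributions matching a moderate/severe
    TBI cohort: median age ~43 (IQR ~29-57), ~82% male, pupillary response
    and Marshall grade frequencies as typically reported."""
    age = float(np.clip(rng.normal(43.0, 21.0), 16.0, 95.0))
    sex = "M" if rng.random() < 0.8165 else "F"
    pupils = rng.choice(
        ["bilateral_reactive", "unilateral_reactive", "bilateral_unreactive"],
        p=[0.5963, 0.2293, 0.1744],
    )
    marshall = rng.choice(["II", "III", "IV", "V"], p=[0.0275, 0.2844, 0.1835, 0.5046])
    gose_1m = int(rng.choice(np.arange(1, 9), p=[0.25, 0.05, 0.2, 0.15, 0.15, 0.1, 0.07, 0.03]))
    # six-month outcomes shift modestly toward recovery among survivors
    gose_6m = gose_1m if gose_1m == 1 else int(min(8, gose_1m + rng.integers(0, 3)))
    return {
        "age": age,
        "sex": str(sex),
        "pupils": str(pupils),
        "marshall_grade": str(marshall),
        "gose_1m": gose_1m,
        "gose_6m": gose_6m,
    }


def default_waveform_sampler(rng: np.random.Generator, covariates: dict) -> WaveformParams:
    """Per-patient waveform parameters: coupling tied to Marshall grade,
    modest between-patient variation elsewhere."""
    coupling = float(
        np.clip(_COUPLING_BY_MARSHALL[covariates["marshall_grade"]] + rng.normal(0, 0.08), -1, 1)
    )
    return WaveformParams(
        duration=3600.0,
        heart_rate=float(rng.uniform(55, 110)),
        resp_rate=float(rng.uniform(12, 22)),
        icp_baseline=float(rng.uniform(8, 25)),
        abp_baseline=float(rng.uniform(75, 110)),
        pulse_amplitude=float(rng.uniform(1.0, 4.0)),
        coupling=coupling,
        seed=int(rng.integers(2**31)),
    )


def make_cohort(
    n_patients: int,
    waveform_params_sampler: Callable[[np.random.Generator, dict], WaveformParams] | None = None,
    artifact_spec: ArtifactSpec | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate ``n_patients`` synthetic patients with covariates, a
    pulsatile recording, and (optionally) injected labeled artifacts.

    Per-patient generators are spawned deterministically from the master
    seed, so cohorts are reproducible and insensitive to patient count
    changes upstream of a given index.
    """
    if n_patients < 1:
        raise InvalidParameterError("n_patients must be >= 1")
    sampler = waveform_params_sampler or default_waveform_sampler
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    cohort = SyntheticCohort()
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        covariates = sample_covariates(rng)
        params = sampler(rng, covariates)
        recording = simulate_pulsatile(params)
        if artifact_spec is not None:
            spec_i = replace(artifact_spec, seed=int(rng.integers(2**31)))
            recording, mask = inject_artifacts(recording, spec_i)
        else:
            mask = ArtifactMask(
                time=recording.time, flags=np.zeros(len(recording), dtype=bool)
            )
        cohort.patients.append(
            Patient(identifier=f"P{i:03d}", recording=recording, covariates=covariates, mask=mask)
        )
    return cohort
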