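"""Synthetic NIRS-BCI cohort generator with known ground truth.

The forward model mirrors the estimation chain: a session's concentration
series is the HRF-convolved task design times planted response amplitudes
(per channel, task and chromophore), plus physiological noise - white
Gaussian noise, a random-walk drift, and Mayer-wave (~0.1 Hz), respiratory
(~0.25 Hz) and cardiac (~1.1 Hz) sinusoids with per-channel random phases.
All noise terms except part of the Mayer band fall outside the 0.005-0.09 Hz
analysis band.  Amplitudes can drift linearly with study day to emulate
training-related reorganization.  Concentrations can be pushed through the
exact inverse of the Beer-Lambert step to produce raw dual-wavelength
intensities, giving the full pipeline a round-trip test bed.

Patient scenarios plant a differential response pattern in the lesioned
hemisphere (stronger response to affected-hand imagery there, the reverse
in the intact hemisphere), yielding positive HbO TRAC on lesioned-side
channels and mildly negative HbO TRAC on intact-side channels; HbR
amplitudes default to -1/3 of HbO.  Healthy scenarios are
hemisphere-symmetric with ordinary contralateral dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage_events import EventSchedule, Montage, SubjectMeta
from .optics import ExtinctionTable, intensities_from_concentrations
from .response_glm import HrfSpec, build_design

CHROMOPHORES = ("HbO", "HbR")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive confound model (concentration units)."""

    # the mix yields a per-session GLM coefficient SE of ~0.1 x a unit
    # planted amplitude on the standard 4-block clinical session
    white_sd: float = 0.5
    drift_sd: float = 0.015  # per-sample random-walk increment
    mayer_amp: float = 0.4  # ~0.1 Hz
    resp_amp: float = 0.3  # ~0.25 Hz
    cardiac_amp: float = 0.3  # ~1.1 Hz

    def __post_init__(self):
        for name in ("white_sd", "drift_sd", "mayer_amp", "resp_amp", "cardiac_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


_NOISE_FREQS = {"mayer_amp": 0.1, "resp_amp": 0.25, "cardiac_amp": 1.1}


@dataclass
class ResponseScenario:
    """Planted truth for one subject: amplitudes, daily drift, noise."""

    amplitude: dict[tuple[str, str, str], float]  # (channel, task, chromophore)
    daily_slope: dict[tuple[str, str, str], float] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if not all(np.isfinite(v) for v in self.amplitude.values()):
            raise ValueError("planted amplitudes must be finite")

    def amplitude_on_day(self, key: tuple[str, str, str], day_index: int) -> float:
        return self.amplitude.get(key, 0.0) + day_index * self.daily_slope.get(key, 0.0)


@dataclass
class SyntheticRecording:
    """One simulated session; holds concentrations and/or raw intensities."""

    fs: float
    schedule: EventSchedule
    channels: list[str]
    truth: ResponseScenario
    concentrations: np.ndarray | None = None  # (n_channels, 2 chromophores, n_times)
    intensities: np.ndarray | None = None  # (n_channels, 2 wavelengths, n_times)
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self):
        n = self.schedule.n_samples
        for arr, name in ((self.concentrations, "concentrations"), (self.intensities, "intensities")):
            if arr is not None and arr.shape != (len(self.channels), 2, n):
                raise ValueError(f"{name} must have shape (n_channels, 2, {n})")
        if self.intensities is not None and np.any(self.intensities <= 0):
            raise ValueError("intensities must be strictly positive")


def fill_hbr(amplitude: dict[tuple[str, str, str], float]) -> dict[tuple[str, str, str], float]:
    """Add HbR amplitudes at -1/3 of HbO wherever they are unspecified."""
    out = dict(amplitude)
    for (ch, task, chrom), v in list(amplitude.items()):
        if chrom == "HbO" and (ch, task, "HbR") not in out:
            out[(ch, task, "HbR")] = -v / 3.0
    return out


def simulate_session(
    montage: Montage,
    schedule: EventSchedule,
    scenario: ResponseScenario,
    day_index: int | None = None,
    hrf: HrfSpec | None = None,
) -> SyntheticRecording:
    """Forward-simulate one session's HbO/HbR concentration series."""
    if schedule.fs <= 0:
        raise ValueError("fs must be positive")
    unknown = {ch for ch, _, _ in scenario.amplitude} - set(montage.channels)
    if unknown:
        raise ValueError(f"scenario channels not in montage: {sorted(unknown)}")
    if day_index is None:
        day_index = schedule.day_index
    design = build_design(schedule, hrf)
    task_cols = {name: design.values[:, j] for j, name in enumerate(design.names)
                 if name not in ("intercept",)}
    n = schedule.n_samples
    fs = schedule.fs
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, schedule.session_id, day_index])
    )
    conc = np.zeros((len(montage.channels), 2, n))
    ns = scenario.noise
    t = np.arange(n) / fs
    for i, ch in enumerate(montage.channels):
        for c, chrom in enumerate(CHROMOPHORES):
            sig = np.zeros(n)
            for task, col in task_cols.items():
                amp = scenario.amplitude_on_day((ch, task, chrom), day_index)
                if amp:
                    sig = sig + amp * col
            if ns.white_sd:
                sig = sig + rng.normal(0.0, ns.white_sd, n)
            if ns.drift_sd:
                sig = sig + np.cumsum(rng.normal(0.0, ns.drift_sd, n))
            for attr, freq in _NOISE_FREQS.items():
                amp = getattr(ns, attr)
                if amp:
                    phase = rng.uniform(0, 2 * np.pi)
                    # continuous-time oscillation sampled at fs (aliases freely)
                    sig = sig + amp * np.sin(2 * np.pi * freq * t + phase)
            conc[i, c] = sig
    return SyntheticRecording(
        fs=fs, schedule=schedule, channels=list(montage.channels),
        truth=scenario, concentrations=conc,
    )


def to_intensities(
    recording: SyntheticRecording,
    baseline_intensity: float = 1.0,
    table: ExtinctionTable | None = None,
) -> SyntheticRecording:
    """Convert a concentration recording to raw dual-wavelength intensities.

    Exact inverse of the optics stage: the round trip through
    ``optical_density`` (with the true baseline) and
    ``concentrations_from_od`` recovers the input to ~1e-9.
    """
    if recording.concentrations is None:
        raise ValueError("recording has no concentration series")
    table = table or ExtinctionTable()
    hbo = recording.concentrations[:, 0, :]
    hbr = recording.concentrations[:, 1, :]
    i1, i2 = intensities_from_concentrations(hbo, hbr, table, baseline_intensity)
    inten = np.stack([i1, i2], axis=1)
    if np.any(inten <= 0) or np.any(~np.isfinite(inten)):
        bad = np.argwhere((inten <= 0) | ~np.isfinite(inten))[0]
        raise ValueError(
            f"concentration excursion drives intensity <= 0 on channel "
            f"{recording.channels[bad[0]]}"
        )
    return replace(recording, intensities=inten, wavelengths=table.wavelengths)


def _patient_amplitudes(
    montage: Montage, lesion_side: str, rng: np.random.Generator,
    jitter_sd: float = 0.08,
) -> dict[tuple[str, str, str], float]:
    """Plant the lesioned-hemisphere differential response pattern.

    Lesioned-hemisphere channels respond 1.0 to affected-hand imagery and
    0.66 to intact-hand imagery (analytic HbO TRAC ~ +0.20); intact-side
    channels respond 0.9 to intact-hand and 1.0 to affected-hand imagery
    (analytic HbO TRAC ~ -0.05).  Per-channel jitter keeps channels
    distinct without flipping the pattern.
    """
    affected = "mi_right" if lesion_side == "left" else "mi_left"
    intact = "mi_left" if affected == "mi_right" else "mi_right"
    amp: dict[tuple[str, str, str], float] = {}
    for ch in montage.channels:
        hemi = montage.hemisphere_of_channel[ch]
        if hemi == lesion_side:
            a_contra, a_ipsi = 1.0, 0.66
        else:
            a_contra, a_ipsi = 0.9, 1.0
        # which hand is contralateral to this channel's hemisphere
        contra_task = affected if hemi == lesion_side else intact
        ipsi_task = intact if contra_task == affected else affected
        amp[(ch, contra_task, "HbO")] = a_contra + rng.normal(0, jitter_sd)
        amp[(ch, ipsi_task, "HbO")] = a_ipsi + rng.normal(0, jitter_sd)
    return fill_hbr(amp)


def _healthy_amplitudes(
    montage: Montage, rng: np.random.Generator, jitter_sd: float = 0.08
) -> dict[tuple[str, str, str], float]:
    """Hemisphere-symmetric contralateral dominance (1.0 contra / 0.8 ipsi)."""
    amp: dict[tuple[str, str, str], float] = {}
    for ch in montage.channels:
        hemi = montage.hemisphere_of_channel[ch]
        contra_task = "mi_right" if hemi == "left" else "mi_left"
        ipsi_task = "mi_left" if contra_task == "mi_right" else "mi_right"
        amp[(ch, contra_task, "HbO")] = 1.0 + rng.normal(0, jitter_sd)
        amp[(ch, ipsi_task, "HbO")] = 0.8 + rng.normal(0, jitter_sd)
    return fill_hbr(amp)


def _session_layout(
    rng: np.random.Generator, group: str,
    n_days: int | None = None, sessions_per_day: int | None = None,
) -> list[tuple[int, int]]:
    """(session_id, day_index) pairs following the protocol ranges.

    Patients: 7-15 days, 1-2 sessions/day, 7-24 sessions total; healthy:
    up to 11 days, one session per day.
    """
    sessions: list[tuple[int, int]] = []
    sid = 0
    if group == "patient":
        days = n_days if n_days is not None else int(rng.integers(7, 16))
        for day in range(1, days + 1):
            k = sessions_per_day if sessions_per_day is not None else int(rng.integers(1, 3))
            for _ in range(k):
                if sessions_per_day is None and len(sessions) >= 24:
                    break
                sessions.append((sid, day))
                sid += 1
    else:
        days = n_days if n_days is not None else int(rng.integers(5, 12))
        k = sessions_per_day if sessions_per_day is not None else 1
        for day in range(1, days + 1):
            for _ in range(k):
                sessions.append((sid, day))
                sid += 1
    return sessions


def build_paper_like_cohort(
    n_patients: int,
    n_healthy: int,
    seed: int = 0,
    montage: Montage | None = None,
    healthy_montage: Montage | None = None,
    noise: NoiseSpec | None = None,
    n_days: int | None = None,
    sessions_per_day: int | None = None,
    lesioned_daily_slope: float = 0.0,
) -> list[tuple[SubjectMeta, ResponseScenario]]:
    """Build subject metadata + planted scenarios for a study-like cohort.

    Lesion sides alternate starting from the left so that a 15-patient
    cohort gets 8 left- and 7 right-sided lesions.  ``lesioned_daily_slope``
    optionally plants a per-day HbO amplitude drift on the lesioned
    hemisphere's contralateral-task response (the substantial-recovery
    pattern); intact-hemisphere channels drift by the opposite sign at half
    magnitude.
    """
    if n_patients < 0 or n_healthy < 0:
        raise ValueError("cohort sizes must be non-negative")
    from .montage_events import load_montage  # local import avoids cycle at init

    montage = montage or load_montage("clinical28")
    healthy_montage = healthy_montage or montage
    root = np.random.default_rng(np.random.SeedSequence([seed]))
    cohort: list[tuple[SubjectMeta, ResponseScenario]] = []
    for i in range(n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, i]))
        lesion = "left" if i % 2 == 0 else "right"
        meta = SubjectMeta(
            subject_id=f"P{i + 1:02d}",
            group="patient",
            lesion_side=lesion,
            sessions=_session_layout(rng, "patient", n_days, sessions_per_day),
            baseline_arat=float(np.clip(rng.normal(30, 15), 1, 57)),
        )
        meta.outcome_arat = float(np.clip(meta.baseline_arat * rng.uniform(1.0, 1.7), 1, 57))
        amp = _patient_amplitudes(montage, lesion, rng)
        slope: dict[tuple[str, str, str], float] = {}
        if lesioned_daily_slope:
            affected = "mi_" + meta.affected_hand
            intact = "mi_left" if affected == "mi_right" else "mi_right"
            for ch in montage.channels:
                hemi = montage.hemisphere_of_channel[ch]
                task = affected if hemi == lesion else intact
                s = lesioned_daily_slope if hemi == lesion else -lesioned_daily_slope / 2
                slope[(ch, task, "HbO")] = s
                slope[(ch, task, "HbR")] = -s / 3.0
        scenario = ResponseScenario(
            amplitude=amp, daily_slope=slope,
            noise=noise or NoiseSpec(),
            seed=int(root.integers(0, 2**31 - 1)),
        )
        cohort.append((meta, scenario))
    for i in range(n_healthy):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, i]))
        meta = SubjectMeta(
            subject_id=f"H{i + 1:02d}",
            group="healthy",
            lesion_side="none",
            sessions=_session_layout(rng, "healthy", n_days, sessions_per_day),
        )
        scenario = ResponseScenario(
            amplitude=_healthy_amplitudes(healthy_montage, rng),
            noise=noise or NoiseSpec(),
            seed=int(root.integers(0, 2**31 - 1)),
        )
        cohort.append((meta, scenario))
    return cohort
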