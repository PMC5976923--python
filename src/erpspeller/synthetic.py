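"""Oddball-paradigm EEG simulator for the RSVP icon speller.

The real cohort this package analyses was never deposited, so analyses run
on synthetic subjects that reproduce the statistical structure the method
assumes: six icons presented 20 times per trial at 300 ms ISI, 12 trials per
session with each icon targeted twice, 11 channels of the 10/20 montage at
256 Hz, and target epochs carrying positive ERP components riding on mixed
1/f ("pink") and white noise.

Two generative phenotypes mirror the high/low speller-performance split:

* ``H-like`` subjects have three positive components (P300, P500, P700).
  P300/P500 are sharp and parietal/occipital-dominant; P700 is broad with a
  fronto-central emphasis.  One component, drawn per subject, is boosted and
  acts as that subject's dominant feature.  Component latencies are stable
  (small per-epoch jitter) and most trials are attended.
* ``L-like`` subjects have a single broad fronto-central P700 and nothing
  in the classical P300 range.  The component's latency fluctuates strongly
  from epoch to epoch and only about half the trials are attended (no ERP
  is elicited in the rest) — the two classic ingredients of speller
  illiteracy, which leave the grand-average P700 visible while degrading
  single-trial decodability.

All randomness flows from explicit seeds through ``numpy`` SeedSequences, so
identical (profile, seed) pairs give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import (CHANNELS, EPOCH_DURATION_S, N_CHANNELS, N_ICONS,
                      N_REPETITIONS, N_SAMPLES, SFREQ_HZ)

__all__ = [
    "ErpPeak",
    "SubjectProfile",
    "EpochRecord",
    "make_profile",
    "dominant_latency",
    "simulate_epoch",
    "simulate_session",
    "write_epoch_table",
    "read_epoch_table",
    "epochs_to_frame",
]

GROUP_H = "H-like"
GROUP_L = "L-like"

# Per-channel gains (max 1) over F3,Fz,F4,C3,Cz,C4,P3,Pz,P4,O1,O2.
_TOPO_P300_HL = (0.2, 0.3, 0.2, 0.5, 0.6, 0.5, 0.9, 1.0, 0.9, 0.8, 0.8)
_TOPO_P500_HL = (0.2, 0.3, 0.2, 0.5, 0.7, 0.5, 0.9, 1.0, 0.9, 0.7, 0.7)
_TOPO_P700_HL = (0.6, 0.7, 0.6, 0.8, 1.0, 0.8, 0.7, 0.7, 0.7, 0.4, 0.4)
_TOPO_P700_LL = (0.8, 0.9, 0.8, 0.9, 1.0, 0.9, 0.3, 0.3, 0.3, 0.1, 0.1)

#: (latency s, base width s, topography) of the H-like components.
_H_COMPONENTS = (
    (0.30, 0.05, _TOPO_P300_HL),
    (0.50, 0.05, _TOPO_P500_HL),
    (0.70, 0.15, _TOPO_P700_HL),
)

BASE_AMPLITUDE_UV = 5.0
DOMINANT_BOOST = 1.6
NOISE_RMS_UV = 10.0
PINK_FRACTION = 0.5

# per-subject jitter ranges (uniform, multiplicative unless noted)
_LATENCY_JITTER_S = 0.02      # additive, +/-
_AMPLITUDE_JITTER = 0.2       # +/- fraction
_WIDTH_JITTER = 0.2           # +/- fraction
_TOPO_JITTER = 0.1            # +/- fraction, renormalised to max 1

# phenotype-level single-trial variability: (per-epoch latency sd s,
# attend-rate range).  Lapsed trials elicit no target ERP at all.
_H_EPOCH_JITTER_S = 0.02
_L_EPOCH_JITTER_S = 0.15
_H_ATTEND_RANGE = (0.85, 0.95)
_L_ATTEND_RANGE = (0.40, 0.60)


@dataclass(frozen=True)
class ErpPeak:
    """One positive ERP component: a Gaussian bump in time with a fixed
    spatial gain pattern."""

    latency_s: float
    amplitude_uV: float
    width_s: float
    topography: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.latency_s < EPOCH_DURATION_S:
            raise ValueError(
                f"peak latency {self.latency_s} s outside the epoch "
                f"(0, {EPOCH_DURATION_S:.3f}) s")
        if len(self.topography) != N_CHANNELS:
            raise ValueError("topography must have one gain per channel")
        if abs(max(self.topography) - 1.0) > 1e-9:
            raise ValueError("topography gains must be normalised to max 1")
        if self.width_s <= 0 or self.amplitude_uV < 0:
            raise ValueError("width must be positive and amplitude non-negative")


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic subject."""

    group_label: str
    peaks: tuple[ErpPeak, ...]
    noise_rms_uV: float = NOISE_RMS_UV
    pink_fraction: float = PINK_FRACTION
    latency_jitter_s: float = 0.0    # per-epoch sd of every peak latency
    attend_rate: float = 1.0         # probability a trial elicits the ERP
    common_evoked_uV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in (GROUP_H, GROUP_L):
            raise ValueError(
                f"unknown group_label {self.group_label!r}; "
                f"expected {GROUP_H!r} or {GROUP_L!r}")
        if self.noise_rms_uV <= 0:
            raise ValueError("noise_rms_uV must be positive")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must be in [0, 1]")
        if self.latency_jitter_s < 0:
            raise ValueError("latency_jitter_s must be non-negative")
        if not 0.0 < self.attend_rate <= 1.0:
            raise ValueError("attend_rate must be in (0, 1]")


@dataclass(frozen=True)
class EpochRecord:
    """One stimulus-locked 11x300 EEG segment with its paradigm metadata."""

    subject_id: str
    session_id: int
    trial_id: int
    icon_id: int
    repetition: int
    is_target: bool
    data: np.ndarray = field(repr=False)


def make_profile(group_label: str, seed: int) -> SubjectProfile:
    """Draw a reproducible subject profile for one generative phenotype.

    H-like subjects receive the three-component complex with one randomly
    boosted dominant component; L-like subjects a single broad P700.  All
    component parameters are jittered within documented ranges so subjects
    differ while staying inside the phenotype.
    """
    if group_label not in (GROUP_H, GROUP_L):
        raise ValueError(
            f"unknown group_label {group_label!r}; expected {GROUP_H!r} or {GROUP_L!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    peaks = []
    if group_label == GROUP_H:
        dominant = int(rng.integers(0, len(_H_COMPONENTS)))
        components = _H_COMPONENTS
        epoch_jitter, attend_range = _H_EPOCH_JITTER_S, _H_ATTEND_RANGE
    else:
        dominant = -1  # single component, no boost
        components = ((0.70, 0.15, _TOPO_P700_LL),)
        epoch_jitter, attend_range = _L_EPOCH_JITTER_S, _L_ATTEND_RANGE
    for i, (lat, width, topo) in enumerate(components):
        amp = BASE_AMPLITUDE_UV * rng.uniform(1 - _AMPLITUDE_JITTER,
                                              1 + _AMPLITUDE_JITTER)
        if i == dominant:
            amp *= DOMINANT_BOOST
        gains = np.asarray(topo) * rng.uniform(1 - _TOPO_JITTER,
                                               1 + _TOPO_JITTER, N_CHANNELS)
        gains = gains / gains.max()
        peaks.append(ErpPeak(
            latency_s=lat + rng.uniform(-_LATENCY_JITTER_S, _LATENCY_JITTER_S),
            amplitude_uV=amp,
            width_s=width * rng.uniform(1 - _WIDTH_JITTER, 1 + _WIDTH_JITTER),
            topography=tuple(np.round(gains, 6)),
        ))
    return SubjectProfile(group_label=group_label, peaks=tuple(peaks),
                          latency_jitter_s=epoch_jitter,
                          attend_rate=float(rng.uniform(*attend_range)),
                          seed=int(seed))


def dominant_latency(profile: SubjectProfile) -> float:
    """Latency (s) of the subject's largest-amplitude injected component."""
    return max(profile.peaks, key=lambda p: p.amplitude_uV).latency_s


def _erp_signal(peaks, t: np.ndarray) -> np.ndarray:
    sig = np.zeros((N_CHANNELS, t.size))
    for pk in peaks:
        bump = pk.amplitude_uV * np.exp(-0.5 * ((t - pk.latency_s) / pk.width_s) ** 2)
        sig += np.asarray(pk.topography)[:, None] * bump
    return sig


_COMMON_EVOKED = ErpPeak(0.20, 1.0, 0.05,
                         (0.3, 0.3, 0.3, 0.4, 0.4, 0.4, 0.7, 0.7, 0.7, 1.0, 1.0))


def _noise(rng: np.random.Generator, pink_fraction: float,
           rms_uV: float) -> np.ndarray:
    """Mixed 1/f-shaped + white noise, scaled to exactly ``rms_uV`` per channel."""
    white = rng.standard_normal((N_CHANNELS, N_SAMPLES))
    if pink_fraction > 0:
        freqs = np.fft.rfftfreq(N_SAMPLES, d=1.0 / SFREQ_HZ)
        shaping = np.zeros_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2, power ~ 1/f
        spec = np.fft.rfft(rng.standard_normal((N_CHANNELS, N_SAMPLES))) * shaping
        pink = np.fft.irfft(spec, n=N_SAMPLES)
        pink /= np.sqrt(np.mean(pink ** 2, axis=1, keepdims=True))
        mix = pink_fraction * pink + (1.0 - pink_fraction) * white
    else:
        mix = white
    mix *= rms_uV / np.sqrt(np.mean(mix ** 2, axis=1, keepdims=True))
    return mix


def simulate_epoch(profile: SubjectProfile, is_target: bool, seed) -> np.ndarray:
    """One 11x300 epoch (microvolts): noise, plus the ERP complex if target.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``; identical
    seeds give bit-identical epochs.  With ``profile.latency_jitter_s > 0``
    every peak's latency is perturbed by a seeded normal draw for this epoch
    (clipped inside the epoch), modelling single-trial latency instability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = _noise(rng, profile.pink_fraction, profile.noise_rms_uV)
    t = np.arange(N_SAMPLES) / SFREQ_HZ
    if profile.common_evoked_uV > 0:
        ce = _COMMON_EVOKED
        data += profile.common_evoked_uV * _erp_signal(
            (ErpPeak(ce.latency_s, 1.0, ce.width_s, ce.topography),), t)
    if is_target:
        peaks = profile.peaks
        if profile.latency_jitter_s > 0:
            lo, hi = 0.01, EPOCH_DURATION_S - 0.01
            peaks = tuple(
                ErpPeak(float(np.clip(p.latency_s + rng.normal(0, profile.latency_jitter_s),
                                      lo, hi)),
                        p.amplitude_uV, p.width_s, p.topography)
                for p in peaks)
        data += _erp_signal(peaks, t)
    return data


def _target_schedule(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Target icon per trial: each icon targeted as evenly as possible, in
    random order (exactly twice each for the standard 12-trial session)."""
    reps = -(-n_trials // N_ICONS)  # ceil
    pool = np.tile(np.arange(N_ICONS), reps)[:n_trials]
    return rng.permutation(pool)


def simulate_session(profile: SubjectProfile, n_trials: int, seed,
                     subject_id: str = "S00", session_id: int = 0) -> list[EpochRecord]:
    """Simulate one session of ``n_trials`` trials (120 epochs per trial).

    Each trial presents the 6 icons 20 times each in a seeded random order;
    exactly one icon is the trial's target.  Per trial a seeded Bernoulli
    draw with ``profile.attend_rate`` decides whether the subject attends;
    in lapsed trials the target icon is still labelled target but its
    epochs carry no ERP (the latent attention state is not recorded, as in
    real data).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_ss, *trial_ss = root.spawn(n_trials + 1)
    sched_rng = np.random.default_rng(sched_ss)
    targets = _target_schedule(n_trials, sched_rng)
    attended = sched_rng.random(n_trials) < profile.attend_rate
    epochs: list[EpochRecord] = []
    for trial, (target, tss) in enumerate(zip(targets, trial_ss)):
        order_ss, *epoch_ss = tss.spawn(N_ICONS * N_REPETITIONS + 1)
        sequence = np.random.default_rng(order_ss).permutation(
            np.repeat(np.arange(N_ICONS), N_REPETITIONS))
        rep_count = np.zeros(N_ICONS, dtype=int)
        for icon, ess in zip(sequence, epoch_ss):
            icon = int(icon)
            is_target = icon == int(target)
            epochs.append(EpochRecord(
                subject_id=subject_id,
                session_id=int(session_id),
                trial_id=trial,
                icon_id=icon,
                repetition=int(rep_count[icon]),
                is_target=is_target,
                data=simulate_epoch(profile, is_target and bool(attended[trial]),
                                    np.random.default_rng(ess)),
            ))
            rep_count[icon] += 1
    return epochs


# --------------------------------------------------------------------------
# Delimited-text epoch table (the on-disk data contract)
# --------------------------------------------------------------------------

_META_KEYS = ("format", "sampling_rate_hz", "n_samples", "channels", "unit")


def epochs_to_frame(epochs: list[EpochRecord]) -> pd.DataFrame:
    """Long table: one row per epoch-channel, columns s000..s299."""
    meta_rows = []
    data_rows = []
    for ep in epochs:
        for ch_i, ch in enumerate(CHANNELS):
            meta_rows.append((ep.subject_id, ep.session_id, ep.trial_id,
                              ep.icon_id, ep.repetition, int(ep.is_target), ch))
            data_rows.append(ep.data[ch_i])
    meta = pd.DataFrame(meta_rows, columns=[
        "subject", "session", "trial", "icon", "repetition", "is_target", "channel"])
    samples = pd.DataFrame(np.asarray(data_rows),
                           columns=[f"s{i:03d}" for i in range(N_SAMPLES)])
    return pd.concat([meta, samples], axis=1)


def write_epoch_table(epochs: list[EpochRecord], path) -> None:
    """Write epochs as tab-delimited text plus a flat key=value sidecar."""
    path = Path(path)
    frame = epochs_to_frame(epochs)
    frame.to_csv(path, sep="\t", index=False, float_format="%.5f")
    meta = {
        "format": "erpspeller-epoch-table-v1",
        "sampling_rate_hz": f"{SFREQ_HZ:g}",
        "n_samples": str(N_SAMPLES),
        "channels": ",".join(CHANNELS),
        "unit": "microvolt",
    }
    with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
        for key in _META_KEYS:
            fh.write(f"{key}={meta[key]}\n")


def read_epoch_table(path) -> list[EpochRecord]:
    """Read a tab-delimited epoch table back into EpochRecords.

    The sidecar, when present, is checked for channel order and sampling
    rate compatibility.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta")
    if sidecar.exists():
        meta = dict(line.strip().split("=", 1)
                    for line in sidecar.read_text().splitlines() if line.strip())
        if meta.get("channels", ",".join(CHANNELS)) != ",".join(CHANNELS):
            raise ValueError(f"{path}: unexpected channel order in sidecar")
        if float(meta.get("sampling_rate_hz", SFREQ_HZ)) != SFREQ_HZ:
            raise ValueError(f"{path}: unexpected sampling rate in sidecar")
    frame = pd.read_csv(path, sep="\t")
    sample_cols = [f"s{i:03d}" for i in range(N_SAMPLES)]
    keys = ["subject", "session", "trial", "icon", "repetition", "is_target"]
    epochs = []
    for key_vals, grp in frame.groupby(keys, sort=True):
        grp = grp.set_index("channel").loc[list(CHANNELS)]
        rec = dict(zip(keys, key_vals))
        epochs.append(EpochRecord(
            subject_id=str(rec["subject"]), session_id=int(rec["session"]),
            trial_id=int(rec["trial"]), icon_id=int(rec["icon"]),
            repetition=int(rec["repetition"]), is_target=bool(rec["is_target"]),
            data=grp[sample_cols].to_numpy(dtype=float),
        ))
    return epochs
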