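"""Build 14x300 CNN input matrices from raw epochs.

Per-icon repetitions are averaged (in non-overlapping groups of ``k``) to
raise SNR, then the three frontal rows are copied below the occipital rows
("frontal wrap") so the 6-row spatial filter also sees occipital-frontal
adjacency.  Averaging and wrapping are both linear, hence commute.
"""

from __future__ import annotations

import numpy as np

from .montage import N_CHANNELS, N_ICONS, N_SAMPLES
from .synthetic import EpochRecord

__all__ = [
    "average_icon",
    "wrap_frontal",
    "build_trial_inputs",
    "training_inputs",
    "grand_average_target",
]

_WRAP_ROWS = 3  # frontal rows F3, Fz, F4 repeated at the bottom


def average_icon(epochs: list[EpochRecord], k: int,
                 baseline: bool = False) -> np.ndarray:
    """Mean of the first ``k`` repetitions of one icon within one trial.

    ``k=1`` returns the single epoch unchanged.  With ``baseline=True`` the
    per-channel epoch mean is subtracted first (off by default; the decoding
    contract applies no filtering or baseline correction).
    """
    if not epochs:
        raise ValueError("average_icon: empty epoch list")
    keys = {(ep.trial_id, ep.icon_id) for ep in epochs}
    if len(keys) != 1:
        raise ValueError(f"average_icon: epochs span several (trial, icon) pairs: {sorted(keys)}")
    if not 1 <= k <= len(epochs):
        raise ValueError(f"average_icon: k={k} outside [1, {len(epochs)}]")
    ordered = sorted(epochs, key=lambda ep: ep.repetition)
    stack = np.stack([ep.data for ep in ordered[:k]])
    if baseline:
        stack = stack - stack.mean(axis=2, keepdims=True)
    return stack.mean(axis=0)


def wrap_frontal(matrix: np.ndarray) -> np.ndarray:
    """11x300 -> 14x300: append copies of the first three (frontal) rows.

    Rejects any other shape, so an already wrapped matrix cannot be wrapped
    twice.
    """
    matrix = np.asarray(matrix)
    if matrix.shape != (N_CHANNELS, N_SAMPLES):
        raise ValueError(
            f"wrap_frontal expects ({N_CHANNELS}, {N_SAMPLES}), got {matrix.shape}")
    return np.concatenate([matrix, matrix[:_WRAP_ROWS]], axis=0)


def _trial_icon_groups(epochs: list[EpochRecord], trial_id: int):
    by_icon: dict[int, list[EpochRecord]] = {}
    target = None
    for ep in epochs:
        if ep.trial_id != trial_id:
            continue
        by_icon.setdefault(ep.icon_id, []).append(ep)
        if ep.is_target:
            target = ep.icon_id
    if not by_icon:
        raise ValueError(f"trial {trial_id} not present in the epoch list")
    missing = set(range(N_ICONS)) - set(by_icon)
    if missing:
        raise ValueError(f"trial {trial_id} is missing icons {sorted(missing)}")
    if target is None:
        raise ValueError(f"trial {trial_id} has no target icon")
    return by_icon, target


def build_trial_inputs(epochs: list[EpochRecord], trial_id: int, k: int,
                       baseline: bool = False):
    """Per-icon averaged + wrapped inputs for one trial.

    Returns ``(inputs, true_target)`` where ``inputs`` is a (6, 14, 300)
    array indexed by icon id.
    """
    by_icon, target = _trial_icon_groups(epochs, trial_id)
    inputs = np.stack([
        wrap_frontal(average_icon(by_icon[icon], k, baseline=baseline))
        for icon in range(N_ICONS)])
    return inputs, target


def training_inputs(epochs: list[EpochRecord], k: int,
                    baseline: bool = False):
    """Labelled sub-average inputs for CNN training.

    Every icon's repetitions in every trial are split into non-overlapping
    groups of ``k`` (remainder dropped); each group is averaged and wrapped.
    With 20 repetitions and ``k=5`` a 12-trial session yields 4 target and
    20 non-target inputs per trial (288 total).

    Returns ``(X, y)``: X (N, 14, 300) and boolean target labels y (N,).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    trials = sorted({ep.trial_id for ep in epochs})
    mats, labels = [], []
    for trial in trials:
        by_icon, target = _trial_icon_groups(epochs, trial)
        for icon in range(N_ICONS):
            reps = sorted(by_icon[icon], key=lambda ep: ep.repetition)
            for start in range(0, len(reps) - k + 1, k):
                chunk = np.stack([ep.data for ep in reps[start:start + k]])
                if baseline:
                    chunk = chunk - chunk.mean(axis=2, keepdims=True)
                mats.append(wrap_frontal(chunk.mean(axis=0)))
                labels.append(icon == target)
    return np.stack(mats), np.asarray(labels, dtype=bool)


def grand_average_target(epochs: list[EpochRecord],
                         baseline: bool = False) -> np.ndarray:
    """Wrapped 14x300 grand average of every target epoch (all trials).

    This is the display/feature basis for the feature-map analysis.
    """
    stack = [ep.data for ep in epochs if ep.is_target]
    if not stack:
        raise ValueError("no target epochs to average")
    arr = np.stack(stack)
    if baseline:
        arr = arr - arr.mean(axis=2, keepdims=True)
    return wrap_frontal(arr.mean(axis=0))
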