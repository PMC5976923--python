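"""Per-trial target identification with the speller's tie-breaking rules.

Each of the six icons gets a binary label from the CNN (positive iff the
target score exceeds the non-target score).  Exactly one icon is then
selected per trial:

* exactly one positive icon -> that icon (``unique``);
* several positives -> the positive icon with the greatest target score
  (``multiple_icons``);
* no positives -> the icon with the greatest target score among all six
  (``no_target``).

Exact score ties resolve to the lowest icon index (deterministic; ties are
measure-zero in practice).  A trial's ERP counts as *detected* when the true
target icon was labelled positive, whichever icon was selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import TrainedCnn, forward
from .montage import N_ICONS

__all__ = ["TrialDecision", "decide_trial", "decide_from_scores", "detection_rate"]


@dataclass(frozen=True)
class TrialDecision:
    trial_id: int
    target_scores: tuple[float, ...]     # first softmax element, per icon
    labels: tuple[bool, ...]             # per-icon binary decisions
    selected_icon: int
    rule_used: str                       # unique | multiple_icons | no_target
    true_target: int
    erp_detected: bool


def decide_trial(model: TrainedCnn, inputs: np.ndarray, true_target: int,
                 trial_id: int = 0) -> TrialDecision:
    """Select exactly one icon for a trial from its six per-icon inputs.

    ``inputs`` is the (6, 14, 300) array of per-icon averaged, wrapped
    matrices in icon order.
    """
    inputs = np.asarray(inputs)
    if inputs.shape[0] != N_ICONS:
        raise ValueError(f"decide_trial expects {N_ICONS} per-icon inputs, "
                         f"got {inputs.shape[0]}")
    scores = forward(model, inputs)[:, 0]
    return decide_from_scores(scores, true_target, trial_id=trial_id)


def decide_from_scores(target_scores, true_target: int,
                       trial_id: int = 0) -> TrialDecision:
    """Apply the tie-breaking rules to six per-icon target scores."""
    scores = np.asarray(target_scores, dtype=np.float64)
    if scores.shape != (N_ICONS,):
        raise ValueError(f"expected {N_ICONS} per-icon scores, got shape {scores.shape}")
    labels = scores > 1.0 - scores          # target score > non-target score
    n_pos = int(labels.sum())
    if n_pos == 1:
        selected = int(np.argmax(labels))
        rule = "unique"
    elif n_pos > 1:
        masked = np.where(labels, scores, -np.inf)
        selected = int(np.argmax(masked))   # argmax ties -> lowest index
        rule = "multiple_icons"
    else:
        selected = int(np.argmax(scores))
        rule = "no_target"
    return TrialDecision(
        trial_id=trial_id,
        target_scores=tuple(float(s) for s in scores),
        labels=tuple(bool(b) for b in labels),
        selected_icon=selected,
        rule_used=rule,
        true_target=int(true_target),
        erp_detected=bool(labels[true_target]),
    )


def detection_rate(decisions: list[TrialDecision]) -> float:
    """Fraction of trials whose true target icon was labelled positive."""
    if not decisions:
        raise ValueError("detection_rate: no decisions")
    return sum(d.erp_detected for d in decisions) / len(decisions)
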