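"""Convolutional feature-map extraction and interpretability statistics.

The trained network is probed with the subject's wrapped grand-average
target ERP.  Post-ReLU activation maps of the two convolutional layers are
the objects of interest: L1 maps (electrode-adjacency structure over time)
and L2 maps (temporal structure per pooled electrode band).

Two per-subject statistics summarise the maps:

* **PSNR** (dB) of an L1 map — peak power over total map power,
  ``10*log10(max^2 / sum(v^2))``.  A map whose weight concentrates in one
  cell scores near 0 dB; diffuse maps score strongly negative.  The subject
  value is the mean over L1 filters.
* **PeT** (s) — peak time of the second layer: L2 maps are averaged across
  filters, collapsed over rows by the mean, and the maximum column is mapped
  back to input time through the cumulative receptive-field geometry (column
  centers, which are unbiased for symmetric peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn import CnnSpec, TrainedCnn, forward_activations, layer_shapes
from .montage import SFREQ_HZ

__all__ = [
    "FeatureMap",
    "rf_geometry",
    "rf_center_times",
    "rf_input_span",
    "extract_maps",
    "psnr_map",
    "subject_psnr",
    "peak_time",
]

_LAYERS = ("L1", "M1", "L2", "M2")


@dataclass(frozen=True)
class FeatureMap:
    """One 2-D post-ReLU activation map with its time axis."""

    layer: str
    filter_index: int
    values: np.ndarray
    rf_center_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("feature maps are post-ReLU and must be non-negative")
        if np.any(np.diff(self.rf_center_times) <= 0):
            raise ValueError("rf_center_times must be strictly increasing")


def rf_geometry(spec: CnnSpec, layer: str) -> tuple[int, int]:
    """(jump, size) of the cumulative receptive field along the time axis.

    ``jump`` is the input-sample stride between adjacent output columns and
    ``size`` the number of input samples a single output column depends on.
    Valid convolution at stride 1 grows size by ``kernel-1`` jumps;
    non-overlapping pooling grows size by ``pool-1`` jumps and multiplies
    the jump by the pool width.
    """
    if layer not in _LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {_LAYERS}")
    stages = [("conv", spec.l1_kernel[1]), ("pool", spec.m1_pool[1]),
              ("conv", spec.l2_kernel[1]), ("pool", spec.m2_pool[1])]
    jump, size = 1, 1
    for stage_layer, (kind, width) in zip(_LAYERS, stages):
        if kind == "conv":
            size += (width - 1) * jump
        else:
            size += (width - 1) * jump
            jump *= width
        if stage_layer == layer:
            return jump, size
    raise AssertionError("unreachable")


def rf_input_span(spec: CnnSpec, layer: str, column: int) -> tuple[int, int]:
    """Inclusive (first, last) input sample a given output column sees."""
    jump, size = rf_geometry(spec, layer)
    first = column * jump
    return first, first + size - 1


def rf_center_times(spec: CnnSpec, layer: str) -> np.ndarray:
    """Receptive-field center time (s) of every column of ``layer``."""
    jump, size = rf_geometry(spec, layer)
    shapes = layer_shapes(spec)
    n_cols = shapes[layer.lower()][1]
    centers = jump * np.arange(n_cols) + (size - 1) / 2.0
    return centers / SFREQ_HZ


def extract_maps(model: TrainedCnn, input_matrix: np.ndarray,
                 layer: str) -> list[FeatureMap]:
    """Post-ReLU activation maps of one conv layer for one input matrix.

    ``layer`` is ``"L1"`` or ``"L2"`` (the pre-pool conv maps: 9x281 and
    4x129 per filter for the default architecture); one map per filter.
    """
    if layer not in ("L1", "L2"):
        raise ValueError(f"extract_maps: unknown layer {layer!r}; expected 'L1' or 'L2'")
    acts = forward_activations(model, input_matrix)[layer.lower()]
    times = rf_center_times(model.spec, layer)
    return [FeatureMap(layer=layer, filter_index=i, values=acts[i],
                       rf_center_times=times)
            for i in range(acts.shape[0])]


def psnr_map(fmap: FeatureMap) -> float:
    """Peak-power-to-total-power ratio of one map, in dB.

    ``10*log10(max(v)^2 / sum(v^2))``: 0 dB for a single nonzero cell,
    ``-10*log10(N)`` for a uniform map of N cells.  An all-zero map has no
    defined peak and is reported as NaN.
    """
    v = np.asarray(fmap.values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("psnr_map: empty map")
    total = float(np.sum(v ** 2))
    if total == 0.0:
        return float("nan")
    return 10.0 * np.log10(float(v.max()) ** 2 / total)


def subject_psnr(maps: list[FeatureMap]) -> float:
    """Mean PSNR over a subject's L1 maps, skipping undefined (all-zero) maps."""
    if not maps:
        raise ValueError("subject_psnr: no maps")
    vals = np.asarray([psnr_map(m) for m in maps])
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def peak_time(maps: list[FeatureMap]) -> float:
    """Peak time (s) of the averaged second-layer maps.

    All maps are averaged element-wise, rows are collapsed by the mean, and
    the maximum column's receptive-field center time is returned (NaN when
    the averaged map is all zero).  Symmetric in the filter order.
    """
    if not maps:
        raise ValueError("peak_time: no maps")
    mean_map = np.mean([np.asarray(m.values, dtype=np.float64) for m in maps], axis=0)
    profile = mean_map.mean(axis=0)
    if np.all(profile == 0):
        return float("nan")
    return float(maps[0].rf_center_times[int(np.argmax(profile))])
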