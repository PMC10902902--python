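"""Differential-pair memristive crossbar for signed weight matrices.

A signed weight ``W_ij`` cannot be stored in one conductance, so each
matrix entry is realized by a pair of devices and read out as the
difference ``dW = G_pos - G_neg`` (doubling the device count).  Weights
are first scaled by ``s = (g_max - g_min) / max(1, max|W|)`` into the
conductance window, then split symmetrically about the mid conductance
``g_mid = (g_min + g_max) / 2``:

    G_pos = g_mid + s*W/2,    G_neg = g_mid - s*W/2

The scale ``s`` is stored on the array so reads (and the sense stage of
``vmm``) invert it exactly.  Supported nonidealities are uniform
conductance quantization, multiplicative Gaussian programming noise and
stuck devices; line resistance and sneak paths are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ConfigError, RangeError, ShapeError


@dataclass
class CrossbarArray:
    """Two conductance matrices realizing one signed weight matrix.

    ``G_pos``/``G_neg`` have the weight matrix's shape; ``scale`` maps
    weight units to conductance units (siemens per weight unit).
    ``levels`` is the quantization grid size used at programming time
    (``None`` means continuous).
    """

    G_pos: np.ndarray
    G_neg: np.ndarray
    g_min: float
    g_max: float
    scale: float
    levels: int | None = None
    noise_sigma: float = 0.0
    stuck_mask: np.ndarray | None = None  # bool (rows, cols, 2): [.., 0]=pos

    def __post_init__(self) -> None:
        if self.G_pos.shape != self.G_neg.shape:
            raise ShapeError("G_pos and G_neg must have identical shape")
        if not (0 < self.g_min < self.g_max):
            raise ConfigError("need 0 < g_min < g_max")

    @property
    def shape(self) -> tuple[int, int]:
        return self.G_pos.shape


def _quantize(G: np.ndarray, g_min: float, g_max: float, levels: int) -> np.ndarray:
    """Snap each conductance to the nearest of `levels` uniform values."""
    step = (g_max - g_min) / (levels - 1)
    return g_min + np.rint((G - g_min) / step) * step


def program_weights(
    W: np.ndarray,
    g_min: float = 1e-5,
    g_max: float = 1e-4,
    levels: int | None = 256,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    stuck_mask: np.ndarray | None = None,
    stuck_value: float | None = None,
) -> CrossbarArray:
    """Map a signed weight matrix onto a differential conductance pair.

    Programming order: scale -> symmetric split -> quantize -> apply
    multiplicative Gaussian noise ``G *= (1 + eps)`` -> clip to
    ``[g_min, g_max]`` -> overwrite stuck devices.  With ``levels=None``
    (continuous) and ``noise_sigma=0`` the mapping is exactly invertible
    by :func:`read_weights`.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if not np.all(np.isfinite(W)):
        raise RangeError("weight matrix contains non-finite entries")
    if not (0 < g_min < g_max):
        raise ConfigError("need 0 < g_min < g_max")
    if levels is not None and levels < 2:
        raise ConfigError("levels must be >= 2 or None for continuous")
    if noise_sigma < 0:
        raise ConfigError("noise_sigma must be >= 0")
    if noise_sigma > 0 and seed is None:
        raise ConfigError("seed is required when noise_sigma > 0")

    span = g_max - g_min
    scale = span / max(1.0, float(np.max(np.abs(W))) if W.size else 1.0)
    Ws = W * scale
    over = np.abs(Ws) > span * (1 + 1e-12)
    if np.any(over):
        i, j = np.argwhere(over)[0]
        raise RangeError(
            f"weight W[{i},{j}]={W[i, j]:g} exceeds the representable range"
        )
    g_mid = 0.5 * (g_min + g_max)
    G_pos = g_mid + Ws / 2.0
    G_neg = g_mid - Ws / 2.0

    if levels is not None:
        G_pos = _quantize(G_pos, g_min, g_max, levels)
        G_neg = _quantize(G_neg, g_min, g_max, levels)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        G_pos = G_pos * (1.0 + rng.normal(0.0, noise_sigma, G_pos.shape))
        G_neg = G_neg * (1.0 + rng.normal(0.0, noise_sigma, G_neg.shape))
    G_pos = np.clip(G_pos, g_min, g_max)
    G_neg = np.clip(G_neg, g_min, g_max)

    if stuck_mask is not None:
        stuck_mask = np.asarray(stuck_mask, dtype=bool)
        if stuck_mask.shape != W.shape + (2,):
            raise ShapeError("stuck_mask must have shape (rows, cols, 2)")
        sv = g_min if stuck_value is None else float(stuck_value)
        G_pos = np.where(stuck_mask[..., 0], sv, G_pos)
        G_neg = np.where(stuck_mask[..., 1], sv, G_neg)

    return CrossbarArray(
        G_pos=G_pos, G_neg=G_neg, g_min=g_min, g_max=g_max,
        scale=scale, levels=levels, noise_sigma=noise_sigma,
        stuck_mask=stuck_mask,
    )


def read_weights(xbar: CrossbarArray) -> np.ndarray:
    """Recover the signed weight matrix ``(G_pos - G_neg) / scale``.

    Stuck devices contribute their stuck conductance, so the read-back
    matrix reflects the defect exactly as the analog hardware would.
    """
    return (xbar.G_pos - xbar.G_neg) / xbar.scale


def vmm(xbar: CrossbarArray, v: np.ndarray) -> np.ndarray:
    """Analog vector-matrix product through the differential pair.

    Input voltages ``v`` drive the rows; each column's differential
    current is ``sum_i (G_pos - G_neg)[i, j] * v[i]`` and the sense
    stage divides by the programming scale, so the result equals
    ``read_weights(xbar).T @ v`` (ideal wires, ideal sensing).  ``v``
    may be a batch ``(B, rows)``; the product is applied row-wise.
    """
    v = np.asarray(v, dtype=float)
    rows = xbar.shape[0]
    if v.shape[-1] != rows:
        raise ShapeError(f"input length {v.shape[-1]} != crossbar rows {rows}")
    dG = xbar.G_pos - xbar.G_neg
    return (v @ dG) / xbar.scale


def save_hdf5(xbar: CrossbarArray, path) -> None:
    """Persist the array state as named numeric datasets."""
    with h5py.File(path, "w") as fh:
        fh["G_pos"] = xbar.G_pos
        fh["G_neg"] = xbar.G_neg
        if xbar.stuck_mask is not None:
            fh["stuck_mask"] = xbar.stuck_mask.astype(np.uint8)
        fh.attrs["g_min"] = xbar.g_min
        fh.attrs["g_max"] = xbar.g_max
        fh.attrs["scale"] = xbar.scale
        fh.attrs["levels"] = -1 if xbar.levels is None else xbar.levels
        fh.attrs["noise_sigma"] = xbar.noise_sigma


def load_hdf5(path) -> CrossbarArray:
    with h5py.File(path, "r") as fh:
        levels = int(fh.attrs["levels"])
        mask = fh["stuck_mask"][()].astype(bool) if "stuck_mask" in fh else None
        return CrossbarArray(
            G_pos=fh["G_pos"][()],
            G_neg=fh["G_neg"][()],
            g_min=float(fh.attrs["g_min"]),
            g_max=float(fh.attrs["g_max"]),
            scale=float(fh.attrs["scale"]),
            levels=None if levels < 0 else levels,
            noise_sigma=float(fh.attrs["noise_sigma"]),
            stuck_mask=mask,
        )
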