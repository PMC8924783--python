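"""Per-window normalization and on-the-fly augmentation.

Normalization (per window, per axis): *centering* subtracts the window mean
of each channel; *z-score* additionally divides by the population standard
deviation (sigma = sqrt(mean((x-mu)^2))), with constant channels mapping to
zeros. Both are idempotent.

Augmentation (training only): *magnitude scaling* multiplies all channels of
a window by one scalar drawn uniformly from ``scale_range``; *3-D rotation*
applies a single random rotation matrix to every timestep's (x, y, z)
vector, mimicking the same movement recorded in a different sensor reference
frame. When both accelerometer and gyroscope triples are present the same
rotation applies to both, since the two sensors share a physical frame.
Augmentations are applied per window before normalization; the evaluation
path never mutates signals beyond the chosen normalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "TransformConfig",
    "center",
    "zscore",
    "scale_magnitude",
    "rotate_3d",
    "random_rotation_matrix",
    "rotation_about_axis",
    "apply_training_transforms",
    "apply_eval_transforms",
]

_NORMALIZATIONS = ("none", "centering", "zscore")


@dataclasses.dataclass
class TransformConfig:
    """Normalization + augmentation settings for one experiment.

    The default — centering with magnitude scaling and no rotation — is the
    best-performing combination for the gyroscope model.
    """

    normalization: str = "centering"
    scale_range: tuple[float, float] | None = (0.8, 1.2)
    rotation: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
        if self.scale_range is not None:
            lo, hi = self.scale_range
            if lo <= 0 or hi < lo:
                raise ValueError("scale_range lower bound must be > 0 and range ordered")


def _check_finite(x: np.ndarray) -> None:
    if not np.isfinite(x).all():
        raise ValueError("window contains non-finite values")


def center(window_channels: np.ndarray) -> np.ndarray:
    """Subtract the per-axis window mean. Accepts (L, C) or batched (..., L, C)."""
    x = np.asarray(window_channels)
    _check_finite(x)
    return x - x.mean(axis=-2, keepdims=True)


def zscore(window_channels: np.ndarray) -> np.ndarray:
    """(x - mu) / sigma per axis with population sigma; constant axes map to 0."""
    x = np.asarray(window_channels)
    _check_finite(x)
    mu = x.mean(axis=-2, keepdims=True)
    sigma = x.std(axis=-2, keepdims=True)
    out = x - mu
    np.divide(out, sigma, out=out, where=sigma > 0)
    out[np.broadcast_to(sigma == 0, out.shape)] = 0.0
    return out


def scale_magnitude(
    window_channels: np.ndarray,
    rng_state: np.random.Generator,
    range: tuple[float, float] = (0.8, 1.2),
) -> np.ndarray:
    """Multiply all channels of the window by one shared Uniform(range) scalar."""
    lo, hi = range
    if lo <= 0:
        raise ValueError("scale range lower bound must be > 0")
    s = rng_state.uniform(lo, hi)
    return np.asarray(window_channels) * s


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis`` by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def random_rotation_matrix(rng_state: np.random.Generator) -> np.ndarray:
    """A random rotation: random orthonormal frame, random angle in (0, 2*pi).

    A random point defines the frame's first basis vector; the rotation is
    taken about the frame's third basis vector by the drawn angle. This is
    equivalent to a uniform random-axis rotation.
    """
    v1 = rng_state.standard_normal(3)
    v1 /= np.linalg.norm(v1)
    v2 = rng_state.standard_normal(3)
    v2 -= v1 * (v1 @ v2)
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    angle = rng_state.uniform(0.0, 2.0 * np.pi)
    return rotation_about_axis(v3, angle)


def rotate_3d(
    window_channels: np.ndarray,
    rng_state: np.random.Generator,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one random rotation to every timestep's 3-vector(s).

    Channels must be one or two (x, y, z) triples per timestep; with both
    sensor triples present the same rotation applies to both.
    """
    x = np.asarray(window_channels)
    c = x.shape[-1]
    if c % 3 != 0:
        raise ValueError(f"channel count {c} is not a multiple of 3")
    R = random_rotation_matrix(rng_state) if rotation is None else rotation
    out = np.empty_like(x)
    for t in range(c // 3):
        out[..., 3 * t : 3 * t + 3] = x[..., 3 * t : 3 * t + 3] @ R.T
    return out


def _normalize(x: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "centering":
        return center(x)
    if normalization == "zscore":
        return zscore(x)
    return x


def apply_training_transforms(
    batch: np.ndarray, cfg: TransformConfig, rng_state: np.random.Generator
) -> np.ndarray:
    """Augment (per-window rotation and/or scaling) then normalize a batch."""
    cfg.validate()
    x = np.asarray(batch, dtype=np.float32)
    if cfg.rotation:
        x = np.stack([rotate_3d(w, rng_state) for w in x])
    if cfg.scale_range is not None:
        s = rng_state.uniform(*cfg.scale_range, size=(len(x), 1, 1)).astype(np.float32)
        x = x * s
    return _normalize(x, cfg.normalization).astype(np.float32, copy=False)


def apply_eval_transforms(batch: np.ndarray, cfg: TransformConfig) -> np.ndarray:
    """Normalization only — evaluation never augments."""
    cfg.validate()
    return _normalize(np.asarray(batch, dtype=np.float32), cfg.normalization).astype(
        np.float32, copy=False
    )
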