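"""Small shared helpers: seeding, frames, logging."""
from __future__ import annotations

import logging
import zlib

import numpy as np

log = logging.getLogger("avtopo")


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the pipeline seed.

    Stages can be rerun independently yet reproducibly: the derived seed
    depends only on the base seed and the stage name, and stays below 2**31.
    """
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def rng_for(base_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(base_seed, stage))


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero vector has no direction")
    return np.asarray(v, dtype=float) / n


def perpendicular_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane perpendicular to ``axis``.

    The reference axis is the coordinate axis least aligned with ``axis`` so the
    frame is stable under small perturbations of the input direction.
    """
    a = unit(axis)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(a)))] = 1.0
    u = unit(np.cross(a, ref))
    v = np.cross(a, u)  # already unit: a ⟂ u
    return u, v


def segment_point_distances(p0, p1, points):
    """Distance from each row of ``points`` to segment p0-p1 (broadcasts)."""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    pts = np.atleast_2d(np.asarray(points, float))
    if L2 == 0.0:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip((pts - p0) @ d / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(pts - proj, axis=-1)


def segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (closed-form clamped solution)."""
    p0, p1, q0, q1 = (np.asarray(x, float) for x in (p0, p1, q0, q1))
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))
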