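"""Full-volume synthesis by sliding-window inference, plus the bicubic
interpolation baseline.

The trained model consumes cubes of ``L`` thick slices.  A full thick
volume is covered by axial windows sharing ``overlap = 1`` thick slice
(in-plane tiles have overlap 0); the final window is anchored at
``D - L`` when the stride does not tile exactly.  Every prediction is
accumulated and coordinates covered more than once are averaged.  The
output has ``(D - 1) * r + 1`` slices and ``dz_out = dz_in / r``.

The baseline interpolates along z only with the Catmull-Rom cubic kernel
(a = -0.5): coincident positions reproduce the thick slices exactly and
linear ramps are interpolated exactly (edge neighbours are linearly
extrapolated, preserving degree-1 polynomials at the volume ends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume, denormalize, normalize_hu


@dataclass
class WindowPlan:
    """Axial window starts plus in-plane tile starts for one volume."""

    z_starts: list[int]
    L: int
    y_starts: list[int]
    x_starts: list[int]
    tile: tuple[int, int]


def _starts_1d(extent: int, length: int, overlap: int) -> list[int]:
    stride = length - overlap
    starts = list(range(0, extent - length + 1, stride))
    if not starts:
        starts = [0]
    if starts[-1] + length < extent:
        starts.append(extent - length)
    return starts


def plan_windows(
    D: int,
    L: int = 8,
    overlap: int = 1,
    H: int | None = None,
    W: int | None = None,
    tile: tuple[int, int] = (256, 256),
) -> WindowPlan:
    """Plan sliding-window coverage of a ``D x H x W`` thick volume."""
    if D < L:
        raise ValueError(
            f"volume has {D} slices but the model needs at least L={L}"
        )
    if not 0 <= overlap < L:
        raise ValueError("overlap must satisfy 0 <= overlap < L")
    z_starts = _starts_1d(D, L, overlap)
    th = min(tile[0], H) if H is not None else tile[0]
    tw = min(tile[1], W) if W is not None else tile[1]
    y_starts = _starts_1d(H, th, 0) if H is not None else [0]
    x_starts = _starts_1d(W, tw, 0) if W is not None else [0]
    return WindowPlan(z_starts=z_starts, L=L, y_starts=y_starts, x_starts=x_starts,
                      tile=(th, tw))


def synthesize_thin(
    model,
    thick: Volume,
    overlap: int = 1,
    tile: tuple[int, int] = (256, 256),
) -> Volume:
    """Synthesize the full thin volume from a thick volume.

    ``model`` needs ``cfg`` (with ``L``, ``r``, ``out_slices``) and a
    ``predict(cube) -> array`` method; predictions are clipped to [0, 1],
    averaged where windows overlap, and denormalized back to HU.
    """
    cfg = model.cfg
    L, r = cfg.L, cfg.r
    D, H, W = thick.shape
    plan = plan_windows(D, L=L, overlap=overlap, H=H, W=W, tile=tile)
    norm = normalize_hu(thick).values
    d_thin = (D - 1) * r + 1
    z_len = cfg.out_slices
    acc = np.zeros((d_thin, H, W), dtype=np.float64)
    count = np.zeros((d_thin, H, W), dtype=np.float64)
    th, tw = plan.tile
    for z0 in plan.z_starts:
        for y0 in plan.y_starts:
            for x0 in plan.x_starts:
                cube = norm[z0 : z0 + L, y0 : y0 + th, x0 : x0 + tw]
                pred = np.clip(model.predict(cube), 0.0, 1.0)
                zt = r * z0
                acc[zt : zt + z_len, y0 : y0 + th, x0 : x0 + tw] += pred
                count[zt : zt + z_len, y0 : y0 + th, x0 : x0 + tw] += 1.0
    if count.min() < 1:
        raise RuntimeError("window plan left some thin coordinates uncovered")
    from .volume_io import NormalizedVolume

    dz, dy, dx = thick.spacing
    out = NormalizedVolume(
        (acc / count).astype(np.float32),
        spacing=(dz / r, dy, dx),
        origin=thick.origin,
    )
    return denormalize(out)


def _catmull_rom(s: np.ndarray) -> np.ndarray:
    """Cubic convolution kernel with a = -0.5 (Catmull-Rom)."""
    s = np.abs(s)
    out = np.zeros_like(s, dtype=np.float64)
    near = s <= 1
    far = (s > 1) & (s <= 2)
    out[near] = 1.5 * s[near] ** 3 - 2.5 * s[near] ** 2 + 1.0
    out[far] = -0.5 * s[far] ** 3 + 2.5 * s[far] ** 2 - 4.0 * s[far] + 2.0
    return out


def bicubic_baseline(thick: Volume, r: int = 5) -> Volume:
    """Axial-only bicubic (Catmull-Rom) interpolation to thin spacing.

    Target positions are ``z = k / r`` in thick-index coordinates for
    ``k = 0 .. (D-1) * r``; in-plane values are untouched.  Coincident
    slices are copied bit-exactly.
    """
    D = thick.n_slices
    if D < 2:
        raise ValueError("bicubic baseline needs at least 2 slices")
    v = thick.values.astype(np.float64)
    # linear extrapolation pad keeps degree-1 polynomials exact at the ends
    vp = np.concatenate(
        [(2 * v[:1] - v[1:2]), v, (2 * v[-1:] - v[-2:-1])], axis=0
    )
    d_thin = (D - 1) * r + 1
    out = np.empty((d_thin,) + thick.shape[1:], dtype=np.float64)
    out[::r] = v  # knots reproduced exactly
    for phase in range(1, r):
        t = phase / r
        w = _catmull_rom(np.array([t + 1.0, t, 1.0 - t, 2.0 - t]))
        i = np.arange(D - 1)  # interval index; target k = i*r + phase
        segment = (
            w[0] * vp[i]
            + w[1] * vp[i + 1]
            + w[2] * vp[i + 2]
            + w[3] * vp[i + 3]
        )
        out[phase::r] = segment
    dz, dy, dx = thick.spacing
    return Volume(
        out.astype(np.float32), spacing=(dz / r, dy, dx), origin=thick.origin
    )
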