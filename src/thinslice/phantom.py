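"""Synthetic paired thin/thick chest-phantom generator.

Real training data for through-plane super-resolution are pairs of 1-mm
and 5-mm CT reconstructed from identical raw data; such pairs are not
publicly deposited.  This module emulates them: a thin (1-mm-like) lung
phantom is drawn procedurally — air-filled ellipsoidal lungs inside a
soft-tissue body shell, vessel trees as random-walk tubes, fissure plates,
and solid/subsolid/calcific nodules, all in plausible HU ranges — and its
thick (5-mm-like) counterpart is produced by a slice-sensitivity-profile
average aligned so that thick slice ``i`` is centred on thin slice
``r*i``.  The pairing obeys ``D_thin = (D_thick - 1) * r + 1``.

Only the HU range and the pairing law are contractual; the geometry is
plumbing that stands in for hospital CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import HU_MAX, HU_MIN, Volume

# HU palette (approximate tissue values)
HU_AIR_LUNG = -900.0
HU_BODY = 40.0
HU_VESSEL = 50.0
HU_FISSURE = -700.0
HU_NODULE = {"solid": 0.0, "subsolid": -500.0, "calcific": 800.0}


@dataclass
class PhantomConfig:
    """Configuration for one synthetic thin volume.

    ``shape_thin[0]`` must be ``1 (mod r)`` so that the degraded thick
    volume has an integer slice count under the ``(D-1)*r+1`` pairing law.
    ``noise_sd`` is Gaussian noise in HU added to the thin volume,
    emulating quantum noise of a thin-slice reconstruction.
    """

    shape_thin: tuple[int, int, int] = (41, 64, 64)
    seed: int = 0
    n_vessels: int = 6
    n_nodules: int = 3
    n_fissures: int = 1
    nodule_kinds: dict = field(
        # proportions follow the study's nodule mix: mostly solid, some
        # calcific, few subsolid
        default_factory=lambda: {"solid": 0.62, "subsolid": 0.07, "calcific": 0.31}
    )
    noise_sd: float = 20.0
    r: int = 5

    def validate(self) -> None:
        d = self.shape_thin[0]
        if d < 1 or (d - 1) % self.r != 0:
            raise ValueError(
                f"thin slice count {d} must satisfy D = k*{self.r}+1 for integer k"
            )
        if min(self.n_vessels, self.n_nodules, self.n_fissures) < 0:
            raise ValueError("structure counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PairedSample:
    """An aligned thin/thick volume pair with SR factor ``r``."""

    thin: Volume
    thick: Volume
    r: int = 5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d_thin, d_thick = self.thin.n_slices, self.thick.n_slices
        if d_thin != (d_thick - 1) * self.r + 1:
            raise ValueError(
                f"pairing law violated: thin={d_thin}, thick={d_thick}, r={self.r}"
            )
        if self.thin.shape[1:] != self.thick.shape[1:]:
            raise ValueError("thin and thick must share the in-plane grid")


def _ellipsoid_mask(shape, center, radii):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def synthesize_phantom(cfg: PhantomConfig) -> Volume:
    """Draw one thin lung-like phantom; deterministic given ``cfg.seed``.

    Returns a :class:`Volume` with ``dz = 1`` (thin spacing) whose
    ``provenance`` attribute-equivalent log is attached under
    ``Volume``-external bookkeeping by :func:`make_paired_sample`; this
    function stores the log on the returned volume as ``volume.provenance``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    D, H, W = cfg.shape_thin
    vol = np.full((D, H, W), HU_MIN, dtype=np.float32)  # outside body: air

    # body shell: soft-tissue ellipsoid filling most of the grid
    body = _ellipsoid_mask((D, H, W), (D / 2, H / 2, W / 2), (D, H * 0.48, W * 0.48))
    vol[body] = HU_BODY

    # two lungs: air-density ellipsoids inside the body
    lungs = np.zeros((D, H, W), dtype=bool)
    for cx in (W * 0.30, W * 0.70):
        lung = _ellipsoid_mask(
            (D, H, W), (D / 2, H * 0.5, cx), (D * 0.55, H * 0.34, W * 0.17)
        )
        lungs |= lung & body
    vol[lungs] = HU_AIR_LUNG

    provenance = {"seed": cfg.seed, "vessels": [], "fissures": [], "nodules": []}

    lung_idx = np.argwhere(lungs)

    # vessels: random-walk tubes through the lungs
    for _ in range(cfg.n_vessels):
        if lung_idx.size == 0:
            break
        pos = lung_idx[rng.integers(len(lung_idx))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction) + 1e-9
        radius = float(rng.uniform(0.8, 1.8))
        n_steps = int(rng.integers(D, 3 * D))
        path = []
        for _ in range(n_steps):
            direction += 0.3 * rng.normal(size=3)
            direction /= np.linalg.norm(direction) + 1e-9
            pos = pos + direction
            zi, yi, xi = (int(round(c)) for c in pos)
            if not (0 <= zi < D and 0 <= yi < H and 0 <= xi < W):
                break
            if not lungs[zi, yi, xi]:
                continue
            path.append((zi, yi, xi))
            rr = int(np.ceil(radius))
            zs, ze = max(0, zi - rr), min(D, zi + rr + 1)
            ys, ye = max(0, yi - rr), min(H, yi + rr + 1)
            xs, xe = max(0, xi - rr), min(W, xi + rr + 1)
            zz, yy, xx = np.ogrid[zs:ze, ys:ye, xs:xe]
            ball = (zz - zi) ** 2 + (yy - yi) ** 2 + (xx - xi) ** 2 <= radius**2
            sub = vol[zs:ze, ys:ye, xs:xe]
            sub[ball & lungs[zs:ze, ys:ye, xs:xe]] = HU_VESSEL
        provenance["vessels"].append({"radius": radius, "n_voxels": len(path)})

    # fissures: thin oblique plates inside the lungs
    for k in range(cfg.n_fissures):
        z0 = float(rng.uniform(0.3 * D, 0.7 * D))
        tilt_y = float(rng.uniform(-0.3, 0.3))
        tilt_x = float(rng.uniform(-0.1, 0.1))
        zz, yy, xx = np.mgrid[:D, :H, :W]
        plane = np.abs(zz - (z0 + tilt_y * (yy - H / 2) + tilt_x * (xx - W / 2))) < 0.8
        vol[plane & lungs] = HU_FISSURE
        provenance["fissures"].append({"z0": z0, "tilt_y": tilt_y, "tilt_x": tilt_x})

    # nodules: disjoint ellipsoids with kind-dependent HU
    kinds = list(cfg.nodule_kinds)
    probs = np.array([cfg.nodule_kinds[k] for k in kinds], dtype=float)
    probs /= probs.sum() if probs.sum() > 0 else 1.0
    placed_masks = np.zeros((D, H, W), dtype=bool)
    n_placed = 0
    attempts = 0
    while n_placed < cfg.n_nodules and attempts < 200 * max(cfg.n_nodules, 1):
        attempts += 1
        if lung_idx.size == 0:
            break
        center = lung_idx[rng.integers(len(lung_idx))]
        radii = rng.uniform(1.5, 4.0, size=3)
        mask = _ellipsoid_mask((D, H, W), center, radii) & lungs
        if not mask.any() or (mask & placed_masks).any():
            continue
        kind = kinds[rng.choice(len(kinds), p=probs)]
        vol[mask] = HU_NODULE[kind]
        placed_masks |= mask
        n_placed += 1
        provenance["nodules"].append(
            {
                "center": [int(c) for c in center],
                "radii": [float(r) for r in radii],
                "kind": kind,
            }
        )

    if cfg.noise_sd > 0:
        vol += rng.normal(0.0, cfg.noise_sd, size=vol.shape).astype(np.float32)
    np.clip(vol, HU_MIN, HU_MAX, out=vol)

    out = Volume(vol, spacing=(1.0, 1.0, 1.0))
    out.provenance = provenance  # bookkeeping side channel, not a dataclass field
    return out


def _profile_weights(r: int, kind: str) -> np.ndarray:
    """Slice-sensitivity profile over offsets -floor(r/2)..floor(r/2)."""
    half = r // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    if kind == "box":
        w = np.ones_like(offsets)
    elif kind == "triangle":
        w = half + 1 - np.abs(offsets)
    elif kind == "gaussian":
        w = np.exp(-0.5 * (offsets / (r / 4.0)) ** 2)
    else:
        raise ValueError(f"unknown profile {kind!r}; use box, triangle or gaussian")
    return w / w.sum()


def degrade_to_thick(thin: Volume, r: int = 5, profile: str = "box") -> Volume:
    """Average a thin volume down to its thick counterpart.

    Thick slice ``i`` is the profile-weighted average of thin slices with
    index in ``[r*i - r//2, r*i + r//2]`` intersected with the volume
    (truncated window at the ends, weights renormalized).  With the
    default box profile this is a plain mean.  The in-plane grid is
    untouched; ``dz`` is multiplied by ``r``.
    """
    d_thin = thin.n_slices
    if (d_thin - 1) % r != 0:
        raise ValueError(
            f"thin slice count {d_thin} must be 1 (mod {r}) to form thick slices"
        )
    d_thick = (d_thin - 1) // r + 1
    half = r // 2
    weights = _profile_weights(r, profile)
    out = np.zeros((d_thick,) + thin.shape[1:], dtype=np.float64)
    for i in range(d_thick):
        zc = r * i
        idx = np.arange(zc - half, zc + half + 1)
        keep = (idx >= 0) & (idx < d_thin)
        w = weights[keep]
        w = w / w.sum()
        out[i] = np.tensordot(w, thin.values[idx[keep]], axes=(0, 0))
    dz, dy, dx = thin.spacing
    return Volume(out.astype(np.float32), spacing=(dz * r, dy, dx), origin=thin.origin)


def make_paired_sample(cfg: PhantomConfig) -> PairedSample:
    """Generate one thin phantom and its degraded thick counterpart."""
    thin = synthesize_phantom(cfg)
    thick = degrade_to_thick(thin, r=cfg.r)
    return PairedSample(
        thin=thin, thick=thick, r=cfg.r, provenance=getattr(thin, "provenance", {})
    )


def make_paired_dataset(
    n: int, base_cfg: PhantomConfig | None = None, seed: int = 0
) -> list[PairedSample]:
    """Generate ``n`` paired samples with per-sample seeds derived from
    ``(seed, index)`` via a seed sequence; deterministic for fixed inputs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_cfg or PhantomConfig()
    samples = []
    for i in range(n):
        child = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        cfg = PhantomConfig(
            shape_thin=base.shape_thin,
            seed=int(child),
            n_vessels=base.n_vessels,
            n_nodules=base.n_nodules,
            n_fissures=base.n_fissures,
            nodule_kinds=dict(base.nodule_kinds),
            noise_sd=base.noise_sd,
            r=base.r,
        )
        samples.append(make_paired_sample(cfg))
    return samples
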