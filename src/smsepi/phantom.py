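"""Digital phantoms, coil sensitivities, contrast-agent dynamics and the
spoiled gradient-echo signal model.

The default structured phantom mimics the calibration object used for
the contrast-dependency experiments: a uniform background compartment
(T1 = 289 ms) containing five doped sub-volumes with
T1 = 211/434/556/953/1257 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomVolume",
    "CoilMaps",
    "BolusModel",
    "SubVolume",
    "PhantomSpec",
    "default_phantom_spec",
    "build_phantom",
    "build_coil_maps",
    "concentration_curve",
    "apply_contrast_agent",
    "spgr_signal",
    "ernst_angle",
]

# default compartment relaxation parameters (ms); background label 1
T1_BACKGROUND = 289.0
T1_SUBVOLUMES = (211.0, 434.0, 556.0, 953.0, 1257.0)


@dataclass(frozen=True)
class PhantomVolume:
    """Ground-truth voxel maps on a 3-D grid (nz, ny, nx)."""

    pd: np.ndarray      # proton density, arbitrary units >= 0
    t1: np.ndarray      # ms, > 0
    t2s: np.ndarray     # ms, > 0
    labels: np.ndarray  # integer compartment map; 0 = empty background
    voxel_size: tuple[float, float, float] = (5.0, 3.1, 3.1)  # mm (z, y, x)

    def __post_init__(self):
        shapes = {m.shape for m in (self.pd, self.t1, self.t2s, self.labels)}
        if len(shapes) != 1:
            raise ValueError("all phantom maps must share one grid shape")
        if np.any(self.pd < 0):
            raise ValueError("proton density must be >= 0")
        if np.any(self.t1 <= 0) or np.any(self.t2s <= 0):
            raise ValueError("t1 and t2s must be > 0 everywhere")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.pd.shape

    @property
    def support(self) -> np.ndarray:
        return self.pd > 0


@dataclass(frozen=True)
class CoilMaps:
    """Smooth complex receive sensitivities.

    ``maps`` is either (n_coils, ny, nx) — one 2-D map shared by all
    slices — or (n_coils, nz, ny, nx) with per-slice sensitivities.
    """

    maps: np.ndarray

    def __post_init__(self):
        if self.maps.ndim not in (3, 4):
            raise ValueError("coil maps must be (n_coils[, nz], ny, nx)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def per_slice(self) -> bool:
        return self.maps.ndim == 4

    def for_slice(self, z: int) -> np.ndarray:
        """Sensitivities seen by slice ``z``, shape (n_coils, ny, nx)."""
        return self.maps[:, z] if self.per_slice else self.maps

    def sos(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass(frozen=True)
class SubVolume:
    """Axis-aligned box (or ellipsoid) compartment inside the phantom."""

    label: int
    t1: float
    t2s: float
    center: tuple[float, float, float]  # fractional grid coordinates in [0,1]
    radius: tuple[float, float, float]  # fractional half-extents
    pd: float = 1.0
    shape: str = "ellipsoid"  # or "box"

    def contains(self, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        dz = (z - self.center[0]) / self.radius[0]
        dy = (y - self.center[1]) / self.radius[1]
        dx = (x - self.center[2]) / self.radius[2]
        if self.shape == "box":
            return (np.abs(dz) <= 1) & (np.abs(dy) <= 1) & (np.abs(dx) <= 1)
        return dz**2 + dy**2 + dx**2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (4, 64, 64)
    voxel_size: tuple[float, float, float] = (5.0, 3.1, 3.1)
    background_t1: float = T1_BACKGROUND
    background_t2s: float = 60.0
    background_pd: float = 1.0
    body_radius: tuple[float, float, float] = (1.0, 0.42, 0.42)  # fractional
    sub_volumes: tuple[SubVolume, ...] = ()


def default_phantom_spec(grid_shape=(4, 64, 64)) -> PhantomSpec:
    """Structured phantom: background + five doped ellipsoids."""
    # z-centers staggered so adjacent slices carry different structure
    centers = [
        (0.30, 0.30, 0.35),
        (0.70, 0.30, 0.65),
        (0.40, 0.52, 0.26),
        (0.60, 0.52, 0.74),
        (0.50, 0.70, 0.50),
    ]
    # T2* chosen < T1 and spread out so relaxometry sees distinct decays
    t2s_values = (25.0, 40.0, 50.0, 70.0, 90.0)
    subs = tuple(
        SubVolume(
            label=i + 2,
            t1=t1,
            t2s=t2s,
            center=c,
            radius=(0.45, 0.10, 0.10),
            pd=1.0,
        )
        for i, (t1, t2s, c) in enumerate(zip(T1_SUBVOLUMES, t2s_values, centers))
    )
    return PhantomSpec(grid_shape=grid_shape, sub_volumes=subs)


def build_phantom(spec: PhantomSpec | None = None) -> PhantomVolume:
    """Voxelize a :class:`PhantomSpec` into ground-truth maps.

    Label 0 is empty space (pd = 0), label 1 the background compartment,
    sub-volumes keep their own labels. Overlapping sub-volumes with
    conflicting relaxation values raise a ``ValueError`` naming them.
    """
    if spec is None:
        spec = default_phantom_spec()
    nz, ny, nx = spec.grid_shape
    if nz < 1 or ny < 1 or nx < 1:
        raise ValueError("grid_shape must be positive")
    z, y, x = np.meshgrid(
        (np.arange(nz) + 0.5) / nz,
        (np.arange(ny) + 0.5) / ny,
        (np.arange(nx) + 0.5) / nx,
        indexing="ij",
    )

    body = SubVolume(
        label=1,
        t1=spec.background_t1,
        t2s=spec.background_t2s,
        center=(0.5, 0.5, 0.5),
        radius=spec.body_radius,
        pd=spec.background_pd,
    )
    inside = body.contains(z, y, x)
    labels = np.where(inside, 1, 0).astype(np.int32)
    pd = np.where(inside, spec.background_pd, 0.0)
    # empty voxels keep physically valid (unused) relaxation values
    t1 = np.full(spec.grid_shape, spec.background_t1)
    t2s = np.full(spec.grid_shape, spec.background_t2s)

    claimed = np.zeros(spec.grid_shape, dtype=np.int32)
    for sv in spec.sub_volumes:
        hit = sv.contains(z, y, x)
        clash = hit & (claimed > 0)
        if np.any(clash):
            other = int(claimed[clash][0])
            prev = next(s for s in spec.sub_volumes if s.label == other)
            if (prev.t1, prev.t2s, prev.pd) != (sv.t1, sv.t2s, sv.pd):
                raise ValueError(
                    f"sub-volumes {other} and {sv.label} overlap with "
                    "conflicting relaxation/pd values"
                )
        labels[hit] = sv.label
        claimed[hit] = sv.label
        pd[hit] = sv.pd
        t1[hit] = sv.t1
        t2s[hit] = sv.t2s
    return PhantomVolume(pd=pd, t1=t1, t2s=t2s, labels=labels,
                         voxel_size=spec.voxel_size)


def _coil_maps_2d(n_coils: int, ny: int, nx: int, smoothness: float,
                  rng: np.random.Generator, angle_offset: float = 0.0) -> np.ndarray:
    ky = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    kx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    # Gaussian low-pass: keep roughly grid/smoothness cycles across the FOV
    win = np.exp(-0.5 * ((ky * smoothness) ** 2 + (kx * smoothness) ** 2) * (2 * math.pi) ** 2)

    from .fourier import ifft2c

    raw = rng.standard_normal((n_coils, ny, nx)) + 1j * rng.standard_normal((n_coils, ny, nx))
    maps = ifft2c(raw * win)

    # deterministic large-scale bias so coils are spatially distinct
    yy = (np.arange(ny) + 0.5) / ny - 0.5
    xx = (np.arange(nx) + 0.5) / nx - 0.5
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    for c in range(n_coils):
        ang = 2 * math.pi * c / n_coils + angle_offset
        cy, cx = 0.6 * math.sin(ang), 0.6 * math.cos(ang)
        dist2 = (Y - cy) ** 2 + (X - cx) ** 2
        maps[c] += 2.0 * np.exp(-dist2 / 0.35) * np.exp(1j * ang)

    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / np.maximum(sos, 1e-12)


def build_coil_maps(n_coils: int, grid: tuple[int, int], smoothness: float = 8.0,
                    seed: int = 0, n_slices: int | None = None) -> CoilMaps:
    """Generate smooth random complex coil sensitivities.

    Maps are band-limited by construction (random low-frequency k-space
    content windowed to ~``grid/smoothness`` cycles across the FOV) and
    normalized so the sum-of-squares magnitude is ~1 inside a central
    disc.  With ``n_slices`` set, each slice sees its own map (the bias
    pattern rotates slowly along z), shape (n_coils, nz, ny, nx).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    ny, nx = grid
    if n_coils == 1:
        shape = (1, ny, nx) if n_slices is None else (1, n_slices, ny, nx)
        return CoilMaps(maps=np.ones(shape, dtype=complex))

    rng = np.random.default_rng(seed)
    if n_slices is None:
        return CoilMaps(maps=_coil_maps_2d(n_coils, ny, nx, smoothness, rng))
    maps = np.empty((n_coils, n_slices, ny, nx), dtype=complex)
    for z in range(n_slices):
        maps[:, z] = _coil_maps_2d(
            n_coils, ny, nx, smoothness, rng,
            angle_offset=2 * math.pi * z / (3 * max(n_slices, 1)),
        )
    return CoilMaps(maps=maps)


@dataclass(frozen=True)
class BolusModel:
    """Gamma-variate contrast-agent bolus with recirculation plateau.

    Vascular concentration (mmol/L)::

        C(t) = peak * gv((t-t0)/beta) + steady * (1 - exp(-(t-t0)/t_rec))

    with ``gv(u) = (u/alpha)^alpha * exp(alpha - u)`` normalized to peak 1
    at ``u = alpha``.  Tissue curves are the vascular curve convolved with
    a single-exponential residue (delayed, dispersed).
    """

    t0: float = 10.0            # s, bolus arrival
    alpha: float = 3.0          # gamma-variate shape
    beta: float = 2.0           # gamma-variate time scale (s)
    peak_conc: float = 1.0      # mmol/L
    r1: float = 4.0             # L mmol^-1 s^-1
    r2s: float = 5.0            # L mmol^-1 s^-1
    recirculation_fraction: float = 0.15
    steady_level: float = 0.15  # mmol/L
    tissue_delay: float = 3.0   # s
    tissue_mtt: float = 8.0     # s, mean transit time of the residue

    def __post_init__(self):
        if not 0 <= self.recirculation_fraction < 1:
            raise ValueError("recirculation_fraction must be in [0, 1)")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma-variate parameters must be > 0")


def _gamma_variate(u: np.ndarray, alpha: float) -> np.ndarray:
    """Peak-normalized gamma variate: (u/alpha)^alpha exp(alpha - u), u >= 0."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = np.exp(alpha * np.log(u[pos] / alpha) + alpha - u[pos])
    return out


def concentration_curve(model: BolusModel, t_grid) -> dict[str, np.ndarray]:
    """Vascular and tissue concentration curves (mmol/L) on ``t_grid`` (s)."""
    t = np.asarray(t_grid, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    u = (t - model.t0) / model.beta
    vascular = model.peak_conc * _gamma_variate(u, model.alpha)
    vascular = vascular + model.steady_level * (
        1.0 - np.exp(-np.clip(t - model.t0, 0, None) / max(3 * model.beta, 1e-9))
    ) * (t >= model.t0)

    # tissue: delayed vascular curve convolved with exp(-t/mtt)/mtt residue
    td = t - model.tissue_delay
    u_d = (td - model.t0) / model.beta
    delayed = model.peak_conc * _gamma_variate(u_d, model.alpha)
    delayed = delayed + model.steady_level * (
        1.0 - np.exp(-np.clip(td - model.t0, 0, None) / max(3 * model.beta, 1e-9))
    ) * (td >= model.t0)
    if t.size > 1:
        dt = float(np.median(np.diff(t)))
        kern_t = np.arange(0, 5 * model.tissue_mtt + dt, dt)
        kern = np.exp(-kern_t / model.tissue_mtt)
        kern /= kern.sum()
        tissue = np.convolve(delayed, kern)[: t.size]
    else:
        tissue = delayed.copy()
    return {"vascular": vascular, "tissue": tissue}


def apply_contrast_agent(volume: PhantomVolume, model: BolusModel,
                         concentration: dict[int, float]) -> PhantomVolume:
    """Return the phantom with relaxation rates raised by the agent.

    ``concentration`` maps compartment label -> C (mmol/L) at the current
    time point; unlisted labels are unmodified.  Rates follow
    ``1/T1 = 1/T1_0 + r1*C`` and ``1/T2* = 1/T2*_0 + r2s*C`` with
    relaxivities in L mmol^-1 s^-1 and times in ms.
    """
    if any(c < 0 for c in concentration.values()):
        raise ValueError("negative concentration")
    cmap = np.zeros(volume.grid_shape)
    for label, c in concentration.items():
        cmap[volume.labels == label] = c
    if not np.any(cmap):
        return volume
    # relaxivity in 1/(mmol/L)/s -> 1/(mmol/L)/ms
    t1 = 1.0 / (1.0 / volume.t1 + model.r1 * 1e-3 * cmap)
    t2s = 1.0 / (1.0 / volume.t2s + model.r2s * 1e-3 * cmap)
    return replace(volume, t1=t1, t2s=t2s)


def spgr_signal(pd, t1, t2s, fa: float, tr: float, te) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal.

    ``S = pd * sin(fa) * (1 - E1) / (1 - cos(fa) * E1) * exp(-te/t2s)``
    with ``E1 = exp(-tr/t1)``; angles in degrees, times in ms.
    """
    fa_rad = np.deg2rad(np.asarray(fa, dtype=float))
    e1 = np.exp(-tr / np.asarray(t1, dtype=float))
    s0 = np.asarray(pd, dtype=float) * np.sin(fa_rad) * (1 - e1) / (1 - np.cos(fa_rad) * e1)
    return s0 * np.exp(-np.asarray(te, dtype=float) / np.asarray(t2s, dtype=float))


def ernst_angle(tr: float, t1: float) -> float:
    """Flip angle (degrees) maximizing the spoiled-GRE steady-state signal:
    ``arccos(exp(-tr/t1))``."""
    if tr <= 0 or t1 <= 0:
        raise ValueError("tr and t1 must be > 0")
    return math.degrees(math.acos(math.exp(-tr / t1)))
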