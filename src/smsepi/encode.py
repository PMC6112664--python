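"""Simulated multiband segmented-EPI acquisitions.

Synthesizes complex multi-coil, multi-echo, multi-segment k-space from a
phantom, either single-band (one k-space per slice) or SMS (slices of a
multiband group summed with their CAIPIRINHA phases).  Slice excitation
is ideal (perfect box profiles) and the longitudinal signal follows the
spoiled-GRE steady state from frame 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fourier import fft1c, fft2c, ifft1c
from .phantom import BolusModel, CoilMaps, PhantomVolume, apply_contrast_agent, concentration_curve, spgr_signal
from .plan import SequencePlan

__all__ = [
    "AcquisitionParams",
    "KSpaceSet",
    "encode_acquisition",
    "collapse_slices",
    "dynamic_phantom_series",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Contrast, noise and artifact settings for one simulated scan.

    Timing fields mirror the :class:`~smsepi.plan.SequencePlan` they are
    used with and are cross-checked at encode time.  ``ghost_phase`` is a
    (constant rad, linear rad/sample) pair applied to odd readout lines
    of each echo train; ``noise_sd`` is the standard deviation of each
    real/imaginary noise component per k-space sample.
    """

    fa: float = 90.0
    tr: float = 261.0
    te_list: tuple[float, ...] = (9.0, 21.5, 34.0)
    n_segments: int = 4
    fov_shift_factor: int = 4
    mb: int = 4
    noise_sd: float = 0.0
    ghost_phase: tuple[float, float] = (0.0, 0.0)
    ets: float = 0.0  # ms per segment
    seed: int = 0

    def __post_init__(self):
        te = tuple(self.te_list)
        object.__setattr__(self, "te_list", te)
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("te_list must be strictly increasing")
        if self.tr <= 0 or any(t <= 0 for t in te):
            raise ValueError("all times must be > 0")
        if self.n_segments < 1 or self.mb < 1 or self.fov_shift_factor < 1:
            raise ValueError("n_segments, mb and fov_shift_factor must be >= 1")

    @classmethod
    def from_plan(cls, plan: SequencePlan, fa: float = 90.0, noise_sd: float = 0.0,
                  ghost_phase=(0.0, 0.0), seed: int = 0) -> "AcquisitionParams":
        return cls(
            fa=fa,
            tr=plan.tr,
            te_list=plan.te_nominal,
            n_segments=plan.n_segments,
            fov_shift_factor=plan.f,
            mb=plan.mb,
            noise_sd=noise_sd,
            ghost_phase=tuple(ghost_phase),
            ets=plan.ets,
            seed=seed,
        )

    def check_against(self, plan: SequencePlan) -> None:
        mismatches = []
        for name, mine, theirs in [
            ("n_segments", self.n_segments, plan.n_segments),
            ("fov_shift_factor", self.fov_shift_factor, plan.f),
            ("mb", self.mb, plan.mb),
            ("te_list", self.te_list, plan.te_nominal),
            ("tr", self.tr, plan.tr),
            ("ets", self.ets, plan.ets),
        ]:
            if mine != theirs:
                mismatches.append(f"{name}: params={mine!r} plan={theirs!r}")
        if mismatches:
            raise ValueError("params/plan mismatch: " + "; ".join(mismatches))


@dataclass
class KSpaceSet:
    """Complex k-space samples plus acquisition metadata.

    ``data`` has shape (n_frames, n_sets, n_echoes, n_coils, n_pe, n_ro)
    where a "set" is a slice for single-band data and an MB slice group
    for SMS data.  ``navigators`` holds three non-phase-encoded readout
    lines per (frame, set, coil): polarities (+, -, +).
    """

    data: np.ndarray
    plan: SequencePlan
    params: AcquisitionParams
    is_sms: bool
    navigators: np.ndarray | None = None  # (n_frames, n_sets, n_coils, 3, n_ro)
    frame_times: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_sets(self) -> int:
        return self.data.shape[1]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]

    @property
    def n_coils(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[-2:]


def caipi_line_phases(plan: SequencePlan, n_pe: int | None = None) -> np.ndarray:
    """Per-line CAIPIRINHA phase factors, shape (mb, n_pe), complex.

    Line ky belongs to segment ``ky % n_segments``; slice ``n`` of a
    group receives ``exp(i * phi(segment, n))`` on that line, which (for
    valid shift factors) equals the shift-theorem phase
    ``exp(2j*pi*ky*n/f)``.  ``n_pe`` may override the plan's matrix size,
    e.g. for downsampled autocalibration grids.
    """
    n_pe = plan.n_pe if n_pe is None else n_pe
    ph = np.empty((plan.mb, n_pe), dtype=complex)
    for ky in range(n_pe):
        seg = ky % plan.n_segments
        for n in range(plan.mb):
            ph[n, ky] = np.exp(1j * plan.caipi_phases[seg][n])
    return ph


def _ghost_line_mask(plan: SequencePlan) -> np.ndarray:
    """Boolean mask over ky of lines acquired under reversed readout
    polarity (odd position within a segment's echo train)."""
    mask = np.zeros(plan.n_pe, dtype=bool)
    for lines in plan.segment_lines:
        for m, ky in enumerate(lines):
            if m % 2 == 1:
                mask[ky] = True
    return mask


def _apply_ghost(kspace: np.ndarray, mask: np.ndarray, const: float, linear: float) -> np.ndarray:
    """Multiply masked ky lines by exp(i*(const + linear*x)) in readout
    hybrid space; ``x`` is the centered sample index."""
    if const == 0.0 and linear == 0.0:
        return kspace
    nx = kspace.shape[-1]
    x = np.arange(nx) - nx // 2
    phase = np.exp(1j * (const + linear * x))
    hyb = ifft1c(kspace, axis=-1)
    hyb[..., mask, :] *= phase
    return fft1c(hyb, axis=-1)


def encode_acquisition(
    volumes,
    coils: CoilMaps,
    plan: SequencePlan,
    params: AcquisitionParams,
    sms: bool | None = None,
    frame_times=None,
    navigators: bool = True,
) -> KSpaceSet:
    """Simulate a (possibly dynamic) acquisition.

    Parameters
    ----------
    volumes
        A single :class:`PhantomVolume` (static scan over
        ``plan.n_frames`` frames) or a sequence with one volume per frame.
    sms
        Collapse multiband groups (default: ``params.mb > 1``).

    Each segment contributes its assigned ky lines to every echo; the
    per-segment echo time includes the echo-time shift ``ets * segment``.
    Noise is i.i.d. complex Gaussian, seeded from ``params.seed``.
    """
    params.check_against(plan)
    if isinstance(volumes, PhantomVolume):
        volumes = [volumes] * plan.n_frames
    volumes = list(volumes)
    n_frames = len(volumes)
    vol0 = volumes[0]
    nz, ny, nx = vol0.grid_shape
    if nz != plan.n_slices:
        raise ValueError(f"phantom has {nz} slices, plan expects {plan.n_slices}")
    if coils.maps.shape[-2:] != (ny, nx):
        raise ValueError("coil grid does not match phantom grid")
    if coils.per_slice and coils.maps.shape[1] != nz:
        raise ValueError("per-slice coil maps do not match slice count")
    maps_z = np.stack([coils.for_slice(z) for z in range(nz)])  # (nz, nc, ny, nx)
    if ny != plan.n_pe:
        raise ValueError(f"phantom PE size {ny} != plan n_pe {plan.n_pe}")
    if sms is None:
        sms = params.mb > 1

    n_echoes = plan.n_echoes
    n_coils = coils.n_coils
    seg_of_ky = np.arange(plan.n_pe) % plan.n_segments
    ghost_mask = _ghost_line_mask(plan)
    g_const, g_lin = params.ghost_phase
    phases = caipi_line_phases(plan)

    # per-slice full k-space for one frame: (nz, n_echoes, n_coils, ny, nx)
    def slice_kspace(vol: PhantomVolume) -> np.ndarray:
        out = np.zeros((nz, n_echoes, n_coils, ny, nx), dtype=complex)
        for i in range(plan.n_segments):
            rows = seg_of_ky == i
            for e in range(n_echoes):
                te = plan.te_effective[i][e]
                sig = spgr_signal(vol.pd, vol.t1, vol.t2s, params.fa, params.tr, te)
                ksp = fft2c(maps_z * sig[:, None, :, :])
                out[:, e, :, rows, :] = np.moveaxis(ksp[:, :, rows, :], 2, 0)
        return out

    rng = np.random.default_rng(params.seed)
    n_sets = plan.n_groups if sms else plan.n_slices
    data = np.zeros((n_frames, n_sets, n_echoes, n_coils, ny, nx), dtype=complex)
    navs = np.zeros((n_frames, n_sets, n_coils, 3, nx), dtype=complex) if navigators else None

    for fidx, vol in enumerate(volumes):
        ksl = slice_kspace(vol)
        ksl = _apply_ghost(ksl, ghost_mask, g_const, g_lin)

        # navigator lines: central (DC) readout at the first echo's signal,
        # middle line acquired under reversed polarity
        sig0 = spgr_signal(vol.pd, vol.t1, vol.t2s, params.fa, params.tr,
                           plan.te_nominal[0])
        nav_line = fft2c(maps_z * sig0[:, None])[:, :, ny // 2, :]  # (nz, nc, nx)
        nav3 = np.repeat(nav_line[:, :, None, :], 3, axis=2)
        if g_const != 0.0 or g_lin != 0.0:
            x = np.arange(nx) - nx // 2
            ph = np.exp(1j * (g_const + g_lin * x))
            hyb = ifft1c(nav3[:, :, 1, :], axis=-1) * ph
            nav3[:, :, 1, :] = fft1c(hyb, axis=-1)

        if sms:
            for g in range(plan.n_groups):
                sl = plan.group_slices(g)
                for n, z in enumerate(sl):
                    data[fidx, g] += ksl[z] * phases[n][None, None, :, None]
                if navigators:
                    navs[fidx, g] = nav3[list(sl)].sum(axis=0)
        else:
            data[fidx] = ksl
            if navigators:
                navs[fidx] = nav3

    if params.noise_sd > 0:
        data += params.noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        if navigators:
            navs += params.noise_sd * (
                rng.standard_normal(navs.shape) + 1j * rng.standard_normal(navs.shape)
            )

    if frame_times is None:
        frame_times = np.arange(n_frames) * plan.dt
    return KSpaceSet(data=data, plan=plan, params=params, is_sms=sms,
                     navigators=navs, frame_times=np.asarray(frame_times, dtype=float))


def collapse_slices(sb: KSpaceSet, plan: SequencePlan | None = None) -> KSpaceSet:
    """Synthesize SMS k-space by summing single-band slice k-spaces with
    their segment-dependent CAIPIRINHA phases.

    The operation is linear in its input and, for noiseless data, equals
    the directly simulated SMS acquisition.
    """
    if sb.is_sms:
        raise ValueError("input is already SMS data")
    plan = plan or sb.plan
    if sb.n_sets != plan.n_slices:
        raise ValueError(
            f"missing slices: single-band set has {sb.n_sets}, plan needs {plan.n_slices}"
        )
    phases = caipi_line_phases(plan)
    n_groups = plan.n_groups
    out = np.zeros(
        (sb.n_frames, n_groups) + sb.data.shape[2:], dtype=complex
    )
    navs = None
    if sb.navigators is not None:
        navs = np.zeros((sb.n_frames, n_groups) + sb.navigators.shape[2:], dtype=complex)
    for g in range(n_groups):
        sl = plan.group_slices(g)
        for n, z in enumerate(sl):
            out[:, g] += sb.data[:, z] * phases[n][None, None, None, :, None]
        if navs is not None:
            navs[:, g] = sb.navigators[:, list(sl)].sum(axis=1)
    return KSpaceSet(data=out, plan=plan, params=sb.params, is_sms=True,
                     navigators=navs, frame_times=sb.frame_times)


def dynamic_phantom_series(
    volume: PhantomVolume,
    model: BolusModel,
    frame_times,
    label_roles: dict[int, str],
) -> list[PhantomVolume]:
    """Phantom snapshots over a bolus passage.

    ``label_roles`` maps compartment label -> "vascular" | "tissue"; the
    matching concentration curve modifies that compartment's T1 and T2*
    frame by frame.
    """
    t = np.asarray(frame_times, dtype=float)
    curves = concentration_curve(model, t)
    series = []
    for k in range(t.size):
        conc = {lab: float(curves[role][k]) for lab, role in label_roles.items()}
        series.append(apply_contrast_agent(volume, model, conc))
    return series
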