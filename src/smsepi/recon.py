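"""Slice-GRAPPA / split-slice-GRAPPA SMS reconstruction.

Kernels are k-space convolution weights mapping collapsed multiband
k-space to the (CAIPIRINHA-shifted) k-space of every individual slice of
the group; split-slice-GRAPPA additionally drives signal leaking from
the other slices of the group to zero.  Pipeline per frame:
navigator-based Nyquist-ghost correction, kernel convolution, removal of
the inter-slice FOV shift in the image domain and sum-of-squares coil
combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .encode import KSpaceSet, caipi_line_phases, collapse_slices, _ghost_line_mask
from .fourier import fft1c, ifft1c, ifft2c
from .plan import SequencePlan

__all__ = [
    "AcsPair",
    "SliceKernel",
    "ReconResult",
    "downsample_acs",
    "prepare_acs_method1",
    "prepare_acs_method2",
    "fit_slice_grappa",
    "fit_split_slice_grappa",
    "apply_kernel",
    "unfold",
    "navigator_phase_correct",
    "sos_combine",
    "reconstruct_series",
    "reconstruct_reference",
]


# ---------------------------------------------------------------------------
# ACS preparation
# ---------------------------------------------------------------------------

def downsample_acs(kspace: np.ndarray, target_grid: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Central k-space crop (symmetric about the DC bin at ``N // 2``).

    Operates on the trailing two axes.  Energy never increases; the DC
    sample is preserved exactly.
    """
    ny, nx = kspace.shape[-2:]
    ty, tx = target_grid
    if ty > ny or tx > nx:
        raise ValueError(f"target grid {target_grid} exceeds source grid {(ny, nx)}")
    y0 = ny // 2 - ty // 2
    x0 = nx // 2 - tx // 2
    return kspace[..., y0 : y0 + ty, x0 : x0 + tx].copy()


@dataclass
class AcsPair:
    """Training data for kernel calibration.

    ``source``: collapsed (or measured-SMS) k-space per group,
    (n_groups, n_echoes, n_coils, ny, nx).
    ``target``: per-slice k-space with the CAIPIRINHA shifts applied,
    (n_groups, mb, n_echoes, n_coils, ny, nx).
    ``slice_sources``: per-slice shifted k-spaces (method 2 only; the
    per-slice addends whose sum is ``source``) — required by
    split-slice-GRAPPA.
    """

    source: np.ndarray
    target: np.ndarray
    contrast_tag: dict
    method: int
    plan: SequencePlan
    slice_sources: np.ndarray | None = None

    @property
    def n_groups(self) -> int:
        return self.source.shape[0]

    @property
    def mb(self) -> int:
        return self.target.shape[1]


def _contrast_tag(ks: KSpaceSet) -> dict:
    p = ks.params
    return {"te_list": tuple(p.te_list), "fa": p.fa, "tr": p.tr}


def _shifted_targets(sb: KSpaceSet, plan: SequencePlan, grid) -> np.ndarray:
    """Group, CAIPIRINHA-shift and crop single-band slice k-spaces.

    Returns (n_groups, mb, n_echoes, n_coils, ty, tx).
    """
    ksp = downsample_acs(sb.data[0], grid)  # (n_slices, n_echoes, n_coils, ty, tx)
    phases = caipi_line_phases(plan, n_pe=grid[0])
    out = np.empty((plan.n_groups, plan.mb) + ksp.shape[1:], dtype=complex)
    for g in range(plan.n_groups):
        for n, z in enumerate(plan.group_slices(g)):
            out[g, n] = ksp[z] * phases[n][None, None, :, None]
    return out


def prepare_acs_method1(sms_acs: KSpaceSet, sb_acs: KSpaceSet,
                        plan: SequencePlan | None = None,
                        grid: tuple[int, int] = (64, 64)) -> AcsPair:
    """ACS from a measured SMS source and a single-band target.

    Both acquisitions must share contrast parameters (TE, FA, TR); the
    single-band targets receive their CAIPIRINHA phase-encode shifts.
    """
    plan = plan or sb_acs.plan
    if not sms_acs.is_sms or sb_acs.is_sms:
        raise ValueError("expected one SMS and one single-band ACS acquisition")
    tag_sms, tag_sb = _contrast_tag(sms_acs), _contrast_tag(sb_acs)
    if tag_sms != tag_sb:
        raise ValueError(
            "ACS contrast mismatch: imaging parameters must be identical for "
            f"the SMS source and single-band target data ({tag_sms} vs {tag_sb})"
        )
    source = downsample_acs(sms_acs.data[0], grid)
    target = _shifted_targets(sb_acs, plan, grid)
    return AcsPair(source=source, target=target, contrast_tag=tag_sb,
                   method=1, plan=plan)


def prepare_acs_method2(sb_acs: KSpaceSet, plan: SequencePlan | None = None,
                        grid: tuple[int, int] = (64, 64)) -> AcsPair:
    """ACS whose source is synthesized by collapsing the single-band
    target slices; retains the per-slice sources for split-slice-GRAPPA."""
    plan = plan or sb_acs.plan
    if sb_acs.is_sms:
        raise ValueError("method 2 needs a single-band acquisition")
    if sb_acs.n_sets != plan.n_slices:
        raise ValueError(
            f"missing slices: got {sb_acs.n_sets}, plan needs {plan.n_slices}"
        )
    target = _shifted_targets(sb_acs, plan, grid)
    source = target.sum(axis=1)  # collapse = sum of shifted slices
    return AcsPair(source=source, target=target, contrast_tag=_contrast_tag(sb_acs),
                   method=2, plan=plan, slice_sources=target.copy())


# ---------------------------------------------------------------------------
# Kernel calibration
# ---------------------------------------------------------------------------

@dataclass
class SliceKernel:
    """Per-slice k-space unfolding weights.

    ``weights`` has shape
    (n_kernel_sets, n_groups, mb, n_coils, n_coils, kh, kw) where the
    leading axis is 1 for the ACS111 policy (single kernel from echo 1)
    or n_echoes for ACS123 (one kernel per echo).
    """

    weights: np.ndarray
    kernel_size: tuple[int, int]
    regularization: float
    algorithm: str  # "sg" | "ssg"
    acs_policy: str  # "acs111" | "acs123"
    plan: SequencePlan
    residual: np.ndarray | None = None  # per (kernel_set, group, slice)

    @property
    def n_kernel_sets(self) -> int:
        return self.weights.shape[0]

    def weights_for_echo(self, e: int) -> np.ndarray:
        return self.weights[0] if self.n_kernel_sets == 1 else self.weights[e]


def _design_matrix(src: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Interior sliding-window design matrix.

    ``src``: (n_coils, ny, nx) -> (n_pos, n_coils*kh*kw) with rows
    ordered by interior target position.
    """
    nc = src.shape[0]
    win = sliding_window_view(src, (kh, kw), axis=(1, 2))  # (nc, py, px, kh, kw)
    py, px = win.shape[1], win.shape[2]
    return win.transpose(1, 2, 0, 3, 4).reshape(py * px, nc * kh * kw)


def _targets_interior(tgt: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """``tgt``: (n_coils, ny, nx) -> (n_pos, n_coils) interior block."""
    nc, ny, nx = tgt.shape
    oy, ox = kh // 2, kw // 2
    block = tgt[:, oy : ny - (kh - 1 - oy), ox : nx - (kw - 1 - ox)]
    return block.reshape(nc, -1).T


def _solve_regularized(gram: np.ndarray, rhs: np.ndarray, lam: float) -> np.ndarray:
    ncol = gram.shape[0]
    scale = np.real(np.trace(gram)) / ncol
    a = gram + lam * scale * np.eye(ncol)
    try:
        return np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "normal equations are singular; retry with regularization λ > 0"
            ) from exc
        raise


def _echo_sets(acs: AcsPair, policy: str) -> list[list[int]]:
    """Echo indices used for each kernel set."""
    n_echoes = acs.source.shape[1]
    if policy == "acs111":
        return [[0]]
    if policy == "acs123":
        return [[e] for e in range(n_echoes)]
    raise ValueError(f"unknown ACS policy {policy!r}")


def fit_slice_grappa(acs: AcsPair, kernel_size: tuple[int, int] = (5, 5),
                     lam: float = 1e-4, acs_policy: str = "acs111") -> SliceKernel:
    """Calibrate slice-GRAPPA weights.

    Per target slice ``s`` and coil ``c`` the weights minimize
    ``||target_{s,c} - K_{s,c} * source||^2 + λ'||K||^2`` over all fully
    interior ACS positions (λ' = λ scaled by the mean Gram diagonal).
    """
    kh, kw = kernel_size
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel_size must be odd")
    ny, nx = acs.source.shape[-2:]
    if ny < kh or nx < kw:
        raise ValueError("ACS grid smaller than kernel")
    n_groups, n_echoes, nc = acs.source.shape[:3]
    mb = acs.mb
    sets = _echo_sets(acs, acs_policy)
    weights = np.zeros((len(sets), n_groups, mb, nc, nc, kh, kw), dtype=complex)
    residual = np.zeros((len(sets), n_groups, mb))
    for k, echoes in enumerate(sets):
        for g in range(n_groups):
            a = np.vstack([_design_matrix(acs.source[g, e], kh, kw) for e in echoes])
            gram = a.conj().T @ a
            for s in range(mb):
                b = np.vstack([_targets_interior(acs.target[g, s, e], kh, kw)
                               for e in echoes])
                w = _solve_regularized(gram, a.conj().T @ b, lam)
                weights[k, g, s] = w.T.reshape(nc, nc, kh, kw)
                residual[k, g, s] = float(
                    np.linalg.norm(a @ w - b) / max(np.linalg.norm(b), 1e-30)
                )
    return SliceKernel(weights=weights, kernel_size=kernel_size, regularization=lam,
                       algorithm="sg", acs_policy=acs_policy, plan=acs.plan,
                       residual=residual)


def fit_split_slice_grappa(acs: AcsPair, kernel_size: tuple[int, int] = (5, 5),
                           lam: float = 1e-4, acs_policy: str = "acs111") -> SliceKernel:
    """Calibrate split-slice-GRAPPA (leak-block) weights.

    Requires method-2 ACS (the per-slice sources must be available).  Per
    target slice ``s`` the weights minimize
    ``sum_{s'} ||K_s * source_{s'} - δ_{ss'} target_s||^2 + λ'||K||^2``,
    i.e. signal originating from the other slices of the group is driven
    to zero.
    """
    if acs.slice_sources is None:
        raise ValueError(
            "split-slice-GRAPPA cannot use unseparated, measured ACS source "
            "data: provide method-2 ACS with per-slice sources"
        )
    kh, kw = kernel_size
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel_size must be odd")
    n_groups, mb, n_echoes, nc = acs.slice_sources.shape[:4]
    sets = _echo_sets(acs, acs_policy)
    weights = np.zeros((len(sets), n_groups, mb, nc, nc, kh, kw), dtype=complex)
    residual = np.zeros((len(sets), n_groups, mb))
    for k, echoes in enumerate(sets):
        for g in range(n_groups):
            mats = [
                np.vstack([_design_matrix(acs.slice_sources[g, sp, e], kh, kw)
                           for e in echoes])
                for sp in range(mb)
            ]
            gram = sum(m.conj().T @ m for m in mats)
            for s in range(mb):
                b = np.vstack([_targets_interior(acs.target[g, s, e], kh, kw)
                               for e in echoes])
                # only the own-slice source block has a nonzero target
                w = _solve_regularized(gram, mats[s].conj().T @ b, lam)
                weights[k, g, s] = w.T.reshape(nc, nc, kh, kw)
                num = sum(
                    np.linalg.norm(mats[sp] @ w - (b if sp == s else 0)) ** 2
                    for sp in range(mb)
                )
                residual[k, g, s] = float(np.sqrt(num) / max(np.linalg.norm(b), 1e-30))
    return SliceKernel(weights=weights, kernel_size=kernel_size, regularization=lam,
                       algorithm="ssg", acs_policy=acs_policy, plan=acs.plan,
                       residual=residual)


# ---------------------------------------------------------------------------
# Unfolding
# ---------------------------------------------------------------------------

def apply_kernel(frame: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Convolve slice weights over a collapsed frame (zero padding).

    ``frame``: (n_coils, ny, nx); ``w``: (nc_t, nc_s, kh, kw) ->
    per-slice k-space (nc_t, ny, nx).
    """
    nc, ny, nx = frame.shape
    nct, ncs, kh, kw = w.shape
    padded = np.pad(frame, ((0, 0), (kh // 2, kh - 1 - kh // 2),
                            (kw // 2, kw - 1 - kw // 2)))
    a = _design_matrix(padded, kh, kw)  # (ny*nx, nc*kh*kw)
    out = a @ w.reshape(nct, ncs * kh * kw).T
    return out.T.reshape(nct, ny, nx)


@dataclass
class ReconResult:
    """Reconstructed images.

    ``slice_images``: magnitudes, (n_frames, n_slices, n_echoes, ny, nx);
    ``coil_images``: complex pre-combination images (optional);
    ``residual``: ACS fit residual per (kernel_set, group, slice), if a
    kernel was involved.
    """

    slice_images: np.ndarray
    coil_images: np.ndarray | None = None
    residual: np.ndarray | None = None


def sos_combine(coil_images: np.ndarray, axis: int = 0) -> np.ndarray:
    """Root-sum-of-squares coil combination along ``axis``."""
    coil_images = np.asarray(coil_images)
    if coil_images.shape[axis] < 1:
        raise ValueError("need at least one coil")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=axis))


def _unshift_image(img: np.ndarray, n: int, f: int) -> np.ndarray:
    """Remove the CAIPIRINHA FOV/f shift of group-slice ``n`` (PE axis -2).

    The encoder's phase ``exp(+2j*pi*ky*n/f)`` shifts the image by
    ``-n*N/f`` pixels along PE, so rolling by ``+n*N/f`` restores it.
    """
    npe = img.shape[-2]
    if (npe * n) % f:
        raise ValueError(f"FOV shift {n}/{f} is not an integer pixel count on {npe} lines")
    return np.roll(img, n * npe // f, axis=-2)


def unfold(frame: np.ndarray, kernel: SliceKernel, group: int = 0) -> np.ndarray:
    """Unfold one collapsed frame into complex per-slice coil images.

    ``frame``: (n_echoes, n_coils, ny, nx) SMS k-space of one group ->
    (mb, n_echoes, n_coils, ny, nx) images with the FOV shift removed.
    """
    n_echoes, nc, ny, nx = frame.shape
    if nc != kernel.weights.shape[3]:
        raise ValueError("coil count does not match kernel training dims")
    mb = kernel.weights.shape[2]
    f = kernel.plan.f
    out = np.empty((mb, n_echoes, nc, ny, nx), dtype=complex)
    for e in range(n_echoes):
        w_e = kernel.weights_for_echo(e)
        for s in range(mb):
            ksl = apply_kernel(frame[e], w_e[group, s])
            out[s, e] = _unshift_image(ifft2c(ksl), s, f)
    return out


# ---------------------------------------------------------------------------
# Nyquist ghost correction
# ---------------------------------------------------------------------------

def estimate_navigator_phase(navigators: np.ndarray) -> tuple[float, float]:
    """Estimate (constant, linear-per-sample) odd-line phase error.

    ``navigators``: (..., 3, n_ro) k-space lines with polarities
    (+, -, +).  The phase ramp between the negative-polarity projection
    and the mean positive-polarity projection is fitted by weighted
    linear regression over the readout position.
    """
    nav = np.asarray(navigators)
    pos = ifft1c(0.5 * (nav[..., 0, :] + nav[..., 2, :]), axis=-1)
    neg = ifft1c(nav[..., 1, :], axis=-1)
    prod = (neg * np.conj(pos)).reshape(-1, nav.shape[-1]).sum(axis=0)
    phase = np.angle(prod)
    wgt = np.abs(prod)
    if not np.any(wgt > 0):
        return 0.0, 0.0
    x = np.arange(nav.shape[-1]) - nav.shape[-1] // 2
    wsum = wgt.sum()
    xm = (wgt * x).sum() / wsum
    pm = (wgt * phase).sum() / wsum
    denom = (wgt * (x - xm) ** 2).sum()
    slope = 0.0 if denom == 0 else float((wgt * (x - xm) * (phase - pm)).sum() / denom)
    const = float(pm - slope * xm)
    return const, slope


def navigator_phase_correct(kspace: np.ndarray, navigators: np.ndarray | None,
                            plan: SequencePlan) -> np.ndarray:
    """Remove the odd-line Nyquist-ghost phase estimated from navigators.

    ``kspace``: (..., n_pe, n_ro).  Lines at odd positions within each
    segment's echo train are multiplied by ``exp(-i(c + s*x))`` in
    readout hybrid space.  A missing navigator set only warns.
    """
    if navigators is None:
        warnings.warn("no navigators available; ghost correction skipped")
        return kspace
    const, slope = estimate_navigator_phase(navigators)
    if const == 0.0 and slope == 0.0:
        return kspace
    mask = _ghost_line_mask(plan)
    nx = kspace.shape[-1]
    x = np.arange(nx) - nx // 2
    corr = np.exp(-1j * (const + slope * x))
    hyb = ifft1c(kspace, axis=-1)
    hyb[..., mask, :] *= corr
    return fft1c(hyb, axis=-1)


# ---------------------------------------------------------------------------
# Series reconstruction
# ---------------------------------------------------------------------------

def reconstruct_series(dynamic: KSpaceSet, kernel: SliceKernel,
                       phase_correct: bool = True,
                       keep_coil_images: bool = False) -> ReconResult:
    """Unfold every frame of an SMS series with one fixed kernel.

    Frames are ghost-corrected (when navigators are present), unfolded
    per group, FOV-unshifted and sum-of-squares combined.  Slice index
    ``n * n_groups + g`` maps group-slice ``n`` of group ``g`` back to
    its global slice position.
    """
    if not dynamic.is_sms:
        raise ValueError("reconstruct_series expects SMS data")
    plan = kernel.plan
    n_frames, n_groups, n_echoes, nc, ny, nx = dynamic.data.shape
    if n_groups != plan.n_groups:
        raise ValueError("group count does not match kernel plan")
    mb = plan.mb
    n_slices = plan.n_slices
    out = np.empty((n_frames, n_slices, n_echoes, ny, nx))
    coil = (np.empty((n_frames, n_slices, n_echoes, nc, ny, nx), dtype=complex)
            if keep_coil_images else None)
    for fr in range(n_frames):
        for g in range(n_groups):
            ksp = dynamic.data[fr, g]
            if phase_correct:
                nav = None if dynamic.navigators is None else dynamic.navigators[fr, g]
                try:
                    ksp = navigator_phase_correct(ksp, nav, plan)
                except Exception as exc:  # noqa: BLE001
                    raise RuntimeError(f"frame {fr}, group {g}: {exc}") from exc
            imgs = unfold(ksp, kernel, group=g)
            for n in range(mb):
                z = plan.group_slices(g)[n]
                out[fr, z] = sos_combine(imgs[n], axis=1)
                if keep_coil_images:
                    coil[fr, z] = imgs[n]
    return ReconResult(slice_images=out, coil_images=coil, residual=kernel.residual)


def reconstruct_reference(sb: KSpaceSet, phase_correct: bool = True) -> ReconResult:
    """Direct single-band reconstruction: ghost correction, inverse FFT
    and sum-of-squares combination (no unfolding)."""
    if sb.is_sms:
        raise ValueError("reference reconstruction expects single-band data")
    plan = sb.plan
    n_frames, n_slices, n_echoes, nc, ny, nx = sb.data.shape
    out = np.empty((n_frames, n_slices, n_echoes, ny, nx))
    for fr in range(n_frames):
        for z in range(n_slices):
            ksp = sb.data[fr, z]
            if phase_correct and sb.navigators is not None:
                ksp = navigator_phase_correct(ksp, sb.navigators[fr, z], plan)
            out[fr, z] = sos_combine(ifft2c(ksp), axis=1)
    return ReconResult(slice_images=out)
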