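"""Acquisition planning for multiband segmented EPI.

Computes segment/line assignment, echo-time tables with echo-time
shifting, the interleaved slice-group acquisition order, the CAIPIRINHA
phase schedule and the scan timing (temporal resolution, total time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequencePlan",
    "ShiftValidation",
    "plan",
    "caipi_phase",
    "validate_shift",
    "interleaved_group_order",
    "format_mmss",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ShiftValidation:
    """Outcome of a FOV-shift feasibility check."""

    ok: bool
    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_shift(f: int, n_segments: int, mb: int) -> ShiftValidation:
    """Check that a FOV/f inter-slice shift is realizable with per-segment
    constant phases.

    A segment owns every ``n_segments``-th phase-encode line, so the
    line-wise shift phase ``2*pi*ky*n/f`` is constant over a segment
    (mod 2*pi) iff ``n_segments * n / f`` is an integer for every
    group-slice index ``n < mb``.
    """
    if f < 1 or n_segments < 1 or mb < 1:
        return ShiftValidation(False, "f, n_segments and mb must all be >= 1")
    for n in range(mb):
        if (n_segments * n) % f != 0:
            return ShiftValidation(
                False,
                f"slice index {n}: lines of one segment would need different "
                f"phases (n_segments*n/f = {n_segments * n}/{f} not integer)",
            )
    return ShiftValidation(True, "per-segment phases consistent")


def caipi_phase(i: int, n: int, f: int, n_segments: int) -> float:
    """CAIPIRINHA phase (radians, in [0, 2*pi)) for segment ``i`` and
    group-slice index ``n`` at FOV shift FOV/f.

    Equals the FFT shift-theorem phase ``2*pi*ky*n/f`` evaluated on any
    line ``ky = i + k*n_segments`` of the segment; raises if that phase is
    not constant across the segment's lines.
    """
    if i < 0 or i >= n_segments:
        raise ValueError(f"segment index {i} outside [0, {n_segments})")
    if n < 0:
        raise ValueError("group-slice index must be >= 0")
    if n > 0 and (n_segments * n) % f != 0:
        raise ValueError(
            f"inconsistent (f={f}, n_segments={n_segments}) for slice {n}: "
            "lines of one segment would require different phases"
        )
    return (TWO_PI * i * n / f) % TWO_PI


def interleaved_group_order(n_groups: int) -> tuple[int, ...]:
    """Cross-talk-avoiding acquisition order: even-indexed groups first,
    then odd-indexed (0,2,4,...,1,3,5,...).

    For exactly four groups the plain even/odd split would put the
    spatially adjacent groups 2 and 1 back to back, so that case is
    reordered (still evens before odds).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups == 4:
        return (2, 0, 3, 1)
    return tuple(range(0, n_groups, 2)) + tuple(range(1, n_groups, 2))


def format_mmss(seconds: float) -> str:
    """Render a duration as "mm:ss", truncating fractional seconds."""
    total = int(seconds)  # floor
    return f"{total // 60}:{total % 60:02d}"


@dataclass(frozen=True)
class SequencePlan:
    """Complete acquisition plan for one protocol.

    ``segment_lines[i]`` lists the 0-based ky indices of segment ``i``;
    ``te_effective[i][e]`` is the echo time of echo ``e`` in segment ``i``
    including the per-segment echo-time shift; ``caipi_phase[i][n]`` is
    the phase (radians) applied to slice ``n`` of a group in segment ``i``.
    """

    n_pe: int
    n_segments: int
    etl: int
    segment_lines: tuple[tuple[int, ...], ...]
    te_nominal: tuple[float, ...]
    te_effective: tuple[tuple[float, ...], ...]
    n_slices: int
    mb: int
    f: int
    group_order: tuple[int, ...]
    caipi_phases: tuple[tuple[float, ...], ...]
    tr: float
    ets: float
    dt: float
    total_time: float
    n_frames: int
    dead_time: float = 0.0

    @property
    def n_groups(self) -> int:
        return self.n_slices // self.mb

    @property
    def t_shot(self) -> float:
        """Duration of one multiband excitation (s): TR / n_groups."""
        return self.tr * 1e-3 / self.n_groups

    @property
    def n_echoes(self) -> int:
        return len(self.te_nominal)

    def group_slices(self, g: int) -> tuple[int, ...]:
        """Global slice indices of MB group ``g`` (equally spaced)."""
        return tuple(g + n * self.n_groups for n in range(self.mb))

    def summary(self) -> str:
        lines = [
            f"PE matrix           : {self.n_pe} lines, {self.n_segments} segments, ETL {self.etl}",
            f"Slices              : {self.n_slices} ({self.n_groups} groups x MB {self.mb}), FOV shift 1/{self.f}",
            f"Group order         : {self.group_order}",
            f"Echo times (ms)     : {list(self.te_nominal)} (ETS {self.ets * 1e3:.0f} us/segment)",
            f"TR / dt             : {self.tr} ms / {self.dt:.3f} s",
            f"Frames / total time : {self.n_frames} / {self.total_time:.1f} s ({format_mmss(self.total_time)})",
        ]
        return "\n".join(lines)


def plan(
    n_pe: int,
    n_segments: int,
    n_slices: int,
    mb: int,
    f: int,
    te_list,
    tr: float,
    ets: float = 0.0,
    n_frames: int = 1,
    dead_time: float = 0.0,
) -> SequencePlan:
    """Build a :class:`SequencePlan`.

    Parameters
    ----------
    n_pe, n_segments
        Phase-encode matrix size and number of EPI segments; each
        segment acquires every ``n_segments``-th line.
    n_slices, mb, f
        Slice count, multiband factor (must divide ``n_slices``) and
        FOV-shift factor (shift = FOV/f along PE).
    te_list, tr, ets
        Nominal echo times (ms), repetition time (ms) and echo-time
        shift per segment (ms).
    n_frames, dead_time
        Number of dynamic frames and extra idle time (s) per frame added
        on top of ``n_segments * n_groups * TR``.
    """
    if n_pe < 1 or n_segments < 1:
        raise ValueError("n_pe and n_segments must be >= 1")
    if n_slices % mb != 0:
        raise ValueError(f"mb = {mb} does not divide n_slices = {n_slices}")
    te_list = tuple(float(t) for t in te_list)
    if any(b <= a for a, b in zip(te_list, te_list[1:])):
        raise ValueError("te_list must be strictly increasing")
    if tr <= 0 or any(t <= 0 for t in te_list):
        raise ValueError("all times must be > 0")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    check = validate_shift(f, n_segments, mb)
    if not check.ok:
        raise ValueError(f"invalid FOV shift factor f={f}: {check.reason}")

    etl = math.ceil(n_pe / n_segments)
    segment_lines = tuple(
        tuple(range(i, n_pe, n_segments)) for i in range(n_segments)
    )
    te_eff = tuple(
        tuple(te + i * ets for te in te_list) for i in range(n_segments)
    )
    phases = tuple(
        tuple(caipi_phase(i, n, f, n_segments) for n in range(mb))
        for i in range(n_segments)
    )
    # all groups are excited within one TR (shot duration TR/n_groups);
    # a frame therefore spans n_segments TR-slots plus any dead time
    n_groups = n_slices // mb
    dt = n_segments * n_groups * (tr * 1e-3 / n_groups) + dead_time
    return SequencePlan(
        n_pe=n_pe,
        n_segments=n_segments,
        etl=etl,
        segment_lines=segment_lines,
        te_nominal=te_list,
        te_effective=te_eff,
        n_slices=n_slices,
        mb=mb,
        f=f,
        group_order=interleaved_group_order(n_groups),
        caipi_phases=phases,
        tr=float(tr),
        ets=float(ets),
        dt=dt,
        total_time=n_frames * dt,
        n_frames=int(n_frames),
        dead_time=float(dead_time),
    )
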