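"""HDF5 persistence for k-space containers and kernels, NIfTI export."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .encode import AcquisitionParams, KSpaceSet
from .plan import SequencePlan, plan as make_plan
from .recon import SliceKernel

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_kernel",
    "load_kernel",
    "export_nifti",
    "load_nifti",
    "export_phantom_maps",
]


def _plan_args(p: SequencePlan) -> dict:
    return {
        "n_pe": p.n_pe,
        "n_segments": p.n_segments,
        "n_slices": p.n_slices,
        "mb": p.mb,
        "f": p.f,
        "te_list": list(p.te_nominal),
        "tr": p.tr,
        "ets": p.ets,
        "n_frames": p.n_frames,
        "dead_time": p.dead_time,
    }


def _write_meta(grp, plan_: SequencePlan, params: AcquisitionParams) -> None:
    grp.attrs["plan"] = json.dumps(_plan_args(plan_))
    d = asdict(params)
    d["te_list"] = list(d["te_list"])
    d["ghost_phase"] = list(d["ghost_phase"])
    grp.attrs["params"] = json.dumps(d)


def _read_meta(grp) -> tuple[SequencePlan, AcquisitionParams]:
    plan_ = make_plan(**json.loads(grp.attrs["plan"]))
    d = json.loads(grp.attrs["params"])
    d["te_list"] = tuple(d["te_list"])
    d["ghost_phase"] = tuple(d["ghost_phase"])
    return plan_, AcquisitionParams(**d)


def save_kspace(path, ks: KSpaceSet) -> None:
    """Write a :class:`KSpaceSet` to an HDF5 container.

    Layout: ``/kspace`` (complex, frame x set x echo x coil x ky x kx),
    ``/navigators``, ``/frame_times``, root attributes carrying the plan
    and acquisition parameters.
    """
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=ks.data)
        if ks.navigators is not None:
            h5.create_dataset("navigators", data=ks.navigators)
        if ks.frame_times is not None:
            h5.create_dataset("frame_times", data=ks.frame_times)
        h5.attrs["is_sms"] = bool(ks.is_sms)
        _write_meta(h5, ks.plan, ks.params)


def load_kspace(path) -> KSpaceSet:
    with h5py.File(path, "r") as h5:
        plan_, params = _read_meta(h5)
        return KSpaceSet(
            data=h5["kspace"][...],
            navigators=h5["navigators"][...] if "navigators" in h5 else None,
            frame_times=h5["frame_times"][...] if "frame_times" in h5 else None,
            plan=plan_,
            params=params,
            is_sms=bool(h5.attrs["is_sms"]),
        )


def save_kernel(path, kernel: SliceKernel) -> None:
    """Persist kernel weights under ``/kernels`` with algorithm/policy
    attributes (appends to an existing container)."""
    with h5py.File(path, "a") as h5:
        if "kernels" in h5:
            del h5["kernels"]
        grp = h5.create_group("kernels")
        grp.create_dataset("weights", data=kernel.weights)
        if kernel.residual is not None:
            grp.create_dataset("residual", data=kernel.residual)
        grp.attrs["kernel_size"] = list(kernel.kernel_size)
        grp.attrs["regularization"] = kernel.regularization
        grp.attrs["algorithm"] = kernel.algorithm
        grp.attrs["acs_policy"] = kernel.acs_policy
        grp.attrs["plan"] = json.dumps(_plan_args(kernel.plan))


def load_kernel(path) -> SliceKernel:
    with h5py.File(path, "r") as h5:
        grp = h5["kernels"]
        return SliceKernel(
            weights=grp["weights"][...],
            residual=grp["residual"][...] if "residual" in grp else None,
            kernel_size=tuple(int(v) for v in grp.attrs["kernel_size"]),
            regularization=float(grp.attrs["regularization"]),
            algorithm=str(grp.attrs["algorithm"]),
            acs_policy=str(grp.attrs["acs_policy"]),
            plan=make_plan(**json.loads(grp.attrs["plan"])),
        )


def export_nifti(path, array: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write an array as NIfTI with a diagonal RAS+ affine built from the
    voxel size (mm).  Spatial axes are expected first (x, y, z[, ...])."""
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def export_phantom_maps(outdir, volume, prefix: str = "phantom") -> list[Path]:
    """Ground-truth maps as one NIfTI per quantity (x, y, z axis order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vz, vy, vx = volume.voxel_size
    written = []
    for name, arr in [("pd", volume.pd), ("t1", volume.t1), ("t2s", volume.t2s),
                      ("labels", volume.labels.astype(float))]:
        path = outdir / f"{prefix}_{name}.nii"
        export_nifti(path, np.transpose(arr, (2, 1, 0)), voxel_size=(vx, vy, vz))
        written.append(path)
    return written
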