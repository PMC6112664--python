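"""Config-driven orchestration of simulate -> train-kernel -> recon ->
qa -> fit-relax, with per-stage logging and a run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import io as sio
from .config import PipelineConfig, write_manifest
from .encode import AcquisitionParams, dynamic_phantom_series, encode_acquisition
from .phantom import BolusModel, build_coil_maps, build_phantom, default_phantom_spec
from .plan import plan as make_plan
from .qa import ediff, huang_mask
from .recon import (
    fit_slice_grappa,
    fit_split_slice_grappa,
    prepare_acs_method1,
    prepare_acs_method2,
    reconstruct_reference,
    reconstruct_series,
)
from .relax import EchoSeries, fit_volume_dynamic, roi_timecourse

log = logging.getLogger("smsepi")

__all__ = ["Pipeline"]


def _timed(stage):
    def deco(fn):
        def wrapper(self, *a, **kw):
            t0 = time.perf_counter()
            log.info("[%s] start", stage)
            out = fn(self, *a, **kw)
            log.info("[%s] done in %.2f s", stage, time.perf_counter() - t0)
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


class Pipeline:
    """Deterministic single-process pipeline over one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- paths ------------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _plan(self):
        c = self.config
        ph, pl = c["phantom"], c["plan"]
        return make_plan(
            n_pe=ph["grid"], n_segments=pl["n_segments"], n_slices=ph["n_slices"],
            mb=pl["mb"], f=pl["f"], te_list=pl["te_list"], tr=pl["tr"],
            ets=pl["ets"], n_frames=pl["n_frames"], dead_time=pl["dead_time"],
        )

    def _phantom(self):
        c = self.config["phantom"]
        spec = default_phantom_spec(grid_shape=(c["n_slices"], c["grid"], c["grid"]))
        scale = c["signal_scale"]
        if scale != 1.0:
            spec = replace(
                spec,
                background_pd=spec.background_pd * scale,
                sub_volumes=tuple(replace(sv, pd=sv.pd * scale)
                                  for sv in spec.sub_volumes),
            )
        return build_phantom(spec)

    # -- stages -----------------------------------------------------------
    @_timed("simulate")
    def simulate(self) -> dict[str, Path]:
        c = self.config
        plan_ = self._plan()
        vol = self._phantom()
        cc = c["coils"]
        coils = build_coil_maps(
            cc["n_coils"], (plan_.n_pe, plan_.n_pe), smoothness=cc["smoothness"],
            seed=c.seed + 7,
            n_slices=c["phantom"]["n_slices"] if cc["per_slice"] else None,
        )
        acq = c["acquisition"]
        params = AcquisitionParams.from_plan(
            plan_, fa=acq["fa"], noise_sd=acq["noise_sd"],
            ghost_phase=(acq["ghost_const"], acq["ghost_linear"]), seed=c.seed,
        )
        bol = c["bolus"]
        if bol["enabled"]:
            model = BolusModel(
                t0=bol["t0"], alpha=bol["alpha"], beta=bol["beta"],
                peak_conc=bol["peak_conc"], r1=bol["r1"], r2s=bol["r2s"],
                steady_level=bol["steady_level"],
                recirculation_fraction=bol["recirculation_fraction"],
                tissue_delay=bol["tissue_delay"], tissue_mtt=bol["tissue_mtt"],
            )
            times = np.arange(plan_.n_frames) * plan_.dt
            roles = {int(l): "vascular" for l in bol["vascular_labels"]}
            roles.update({int(l): "tissue" for l in bol["tissue_labels"]})
            volumes = dynamic_phantom_series(vol, model, times, roles)
        else:
            volumes = [vol] * plan_.n_frames

        # pre-bolus single-frame ACS (noise level of the acquisition)
        acs_params = replace(params, seed=c.seed + 1)
        sb_acs = encode_acquisition(vol, coils, plan_, acs_params, sms=False)
        sms_acs = encode_acquisition(vol, coils, plan_, acs_params, sms=True)
        dynamic = encode_acquisition(volumes, coils, plan_, params, sms=True)
        reference = encode_acquisition(volumes, coils, plan_,
                                       replace(params, seed=c.seed + 2), sms=False)
        arts = {}
        for name, ks in [("acs_sb", sb_acs), ("acs_sms", sms_acs),
                         ("dynamic", dynamic), ("reference", reference)]:
            p = self.path(f"{name}.h5")
            sio.save_kspace(p, ks)
            arts[name] = p
        arts.update(
            {f"truth_{pth.stem.split('_')[-1]}": pth
             for pth in sio.export_phantom_maps(self.outdir, vol)}
        )
        write_manifest(self.outdir, c, arts, "simulate")
        return arts

    @_timed("train-kernel")
    def train_kernel(self) -> Path:
        c = self.config["recon"]
        sb = sio.load_kspace(self.path("acs_sb.h5"))
        grid = sb.grid
        if c["method"] == 1:
            sms = sio.load_kspace(self.path("acs_sms.h5"))
            acs = prepare_acs_method1(sms, sb, grid=grid)
        elif c["method"] == 2:
            acs = prepare_acs_method2(sb, grid=grid)
        else:
            raise ValueError(f"unknown ACS method {c['method']}")
        fitter = {"sg": fit_slice_grappa, "ssg": fit_split_slice_grappa}[c["algo"]]
        kernel = fitter(acs, kernel_size=tuple(c["kernel_size"]), lam=c["lam"],
                        acs_policy=c["policy"])
        p = self.path("kernel.h5")
        sio.save_kernel(p, kernel)
        write_manifest(self.outdir, self.config, {"kernel": p}, "train-kernel")
        return p

    @_timed("recon")
    def recon(self) -> Path:
        kernel = sio.load_kernel(self.path("kernel.h5"))
        dyn = sio.load_kspace(self.path("dynamic.h5"))
        res = reconstruct_series(dyn, kernel,
                                 phase_correct=self.config["recon"]["phase_correct"])
        p = self.path("images.h5")
        with h5py.File(p, "w") as h5:
            h5.create_dataset("images", data=res.slice_images)
            if res.residual is not None:
                h5.create_dataset("residual", data=res.residual)
            h5.attrs["frame_times"] = (
                dyn.frame_times if dyn.frame_times is not None
                else np.arange(res.slice_images.shape[0]) * kernel.plan.dt
            )
            h5.attrs["te_list"] = list(kernel.plan.te_nominal)
        # 4D NIfTI per echo: (x, y, z, t)
        vz, vy, vx = self._phantom().voxel_size
        for e in range(res.slice_images.shape[2]):
            vol4 = np.transpose(res.slice_images[:, :, e], (3, 2, 1, 0))
            sio.export_nifti(self.path(f"recon_echo{e + 1}.nii"), vol4,
                             voxel_size=(vx, vy, vz))
        write_manifest(self.outdir, self.config, {"images": p}, "recon")
        return p

    @_timed("qa")
    def qa(self) -> Path:
        with h5py.File(self.path("images.h5"), "r") as h5:
            imgs = h5["images"][...]
        ref = reconstruct_reference(sio.load_kspace(self.path("reference.h5")))
        mask = huang_mask(ref.slice_images[0, :, 0])
        rows = []
        for e in range(imgs.shape[2]):
            r = ediff(imgs[0, :, e], ref.slice_images[0, :, e], mask)
            rows.append({"echo": e + 1, "mean_ediff": r.mean, "std_ediff": r.std,
                         "n_excluded": r.n_excluded})
            sio.export_nifti(self.path(f"ediff_echo{e + 1}.nii"),
                             np.transpose(r.map, (2, 1, 0)))
        df = pd.DataFrame(rows)
        p = self.path("qa_summary.csv")
        df.to_csv(p, index=False)
        self._qa_histograms(imgs, ref.slice_images, mask)
        write_manifest(self.outdir, self.config, {"qa_summary": p}, "qa")
        return p

    def _qa_histograms(self, imgs, ref, mask) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        r = ediff(imgs[0, :, 0], ref[0, :, 0], mask)
        ax.hist(r.map[mask & (r.map > 0)], bins=50)
        ax.set_xlabel("normalized subtraction error")
        ax.set_ylabel("voxels")
        fig.tight_layout()
        fig.savefig(self.path("ediff_hist.png"), dpi=100)
        plt.close(fig)

    @_timed("fit-relax")
    def fit_relax(self) -> Path:
        with h5py.File(self.path("images.h5"), "r") as h5:
            imgs = h5["images"][...]
            te_list = list(h5.attrs["te_list"])
            frame_times = np.asarray(h5.attrs["frame_times"])
        # (frames, slices, echoes, ny, nx) -> (frames, echoes, slices, ny, nx)
        series = EchoSeries(te_list=te_list,
                            signals=np.transpose(imgs, (0, 2, 1, 3, 4)),
                            frame_times=frame_times)
        mask = huang_mask(imgs[0, :, 0])
        t2s_max = self.config["relax"]["t2s_max"]
        s0, t2s, info = fit_volume_dynamic(series, mask, t2s_bounds=(0.1, t2s_max))
        log.info("[fit-relax] %(n_fits)d fits, %(n_fallback)d fallbacks", info)
        vz, vy, vx = self._phantom().voxel_size
        sio.export_nifti(self.path("s0.nii"), np.transpose(s0, (3, 2, 1, 0)),
                         voxel_size=(vx, vy, vz))
        sio.export_nifti(self.path("t2s.nii"), np.transpose(t2s, (3, 2, 1, 0)),
                         voxel_size=(vx, vy, vz))
        # ROI curves per phantom compartment
        labels = self._phantom().labels
        rows = []
        for lab in np.unique(labels[labels > 0]):
            roi = (labels == lab) & mask
            if not roi.any():
                continue
            for name, maps in [("s0", s0), ("t2s", t2s)]:
                mean, std = roi_timecourse(maps, roi)
                for t, m, sd in zip(frame_times, mean, std):
                    rows.append({"label": int(lab), "quantity": name,
                                 "frame_time": float(t), "mean": float(m),
                                 "std": float(sd)})
        p = self.path("roi_curves.csv")
        pd.DataFrame(rows).to_csv(p, index=False)
        write_manifest(self.outdir, self.config,
                       {"s0": self.path("s0.nii"), "t2s": self.path("t2s.nii"),
                        "roi_curves": p}, "fit-relax")
        return p

    def run_all(self) -> dict:
        """Execute every stage in acquisition/postprocessing order and
        return a summary report."""
        stages = [("simulate", self.simulate), ("train-kernel", self.train_kernel),
                  ("recon", self.recon), ("qa", self.qa),
                  ("fit-relax", self.fit_relax)]
        for name, fn in stages:
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        report = {
            "qa": pd.read_csv(self.path("qa_summary.csv")).to_dict("records"),
            "manifest": str(self.path("manifest.json")),
        }
        (self.path("report.json")).write_text(json.dumps(report, indent=2))
        return report
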