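"""End-to-end orchestration: phantom/volume -> preprocess -> segment -> mesh
-> centerline -> CSA profile -> validation report.

Configuration is a single nested mapping (YAML on disk) validated up front;
every artifact is written with a manifest recording the configuration hash
and package versions, and identical config + seed reproduces byte-identical
CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from . import __version__
from .centerline import bezier_refine, extract_main_path, smooth_points, thin_skeleton
from .csa import build_profile
from .mesh import curvature_smooth, marching_cubes
from .phantom import PhantomSpec, generate_phantom
from .preprocess import PSFModel, bilateral_filter, selective_deblur, wiener_deconvolve
from .segmentation import (
    GrowParams,
    classify_calcific,
    detect_seeds,
    largest_component,
    region_grow,
)
from .validation import align_series, read_pullback
from .volume_io import Volume, read_volume, write_mask, write_mesh, write_volume

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PreprocessConfig:
    psf_sigma: float = 0.6  # mm
    nsr: float = 0.002
    selective_threshold: float | None = None  # HU; None disables blending
    bilateral: tuple[float, float] | None = None  # (sigma_spatial mm, sigma_range HU)

    def validate(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("preprocess.psf_sigma must be positive")
        if self.nsr < 0:
            raise ValueError("preprocess.nsr must be >= 0")
        if self.bilateral is not None and (
            len(self.bilateral) != 2 or any(s <= 0 for s in self.bilateral)
        ):
            raise ValueError("preprocess.bilateral must be two positive sigmas")


@dataclass
class SegmentConfig:
    seed_threshold: float = 350.0  # HU
    sphere_radius: float = 2.0  # mm
    bin_width: float = 10.0  # HU
    connectivity: int = 26
    calcific_threshold: float | None = 700.0  # HU; None skips classification
    max_voxels: int = 500_000

    def validate(self) -> None:
        GrowParams(
            seed_threshold=self.seed_threshold,
            sphere_radius=self.sphere_radius,
            bin_width=self.bin_width,
            connectivity=self.connectivity,
            max_voxels=self.max_voxels,
        )

    def grow_params(self) -> GrowParams:
        return GrowParams(
            seed_threshold=self.seed_threshold,
            sphere_radius=self.sphere_radius,
            bin_width=self.bin_width,
            connectivity=self.connectivity,
            max_voxels=self.max_voxels,
        )


@dataclass
class MeshConfig:
    source: str = "hu"  # hu (sub-voxel iso on deconvolved HU) | mask (binary 0.5)
    iso: float | None = None  # HU iso; None = midpoint of lumen/background means
    smooth_iterations: int = 20
    mask_dilation: int = 2  # voxels of context kept around the lumen for hu mode

    def validate(self) -> None:
        if self.source not in ("hu", "mask"):
            raise ValueError("mesh.source must be 'hu' or 'mask'")
        if self.smooth_iterations < 0:
            raise ValueError("mesh.smooth_iterations must be >= 0")


@dataclass
class CenterlineConfig:
    smooth_window: int = 5
    samples_per_segment: int = 10

    def validate(self) -> None:
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("centerline.smooth_window must be odd and >= 3")


@dataclass
class CsaConfig:
    step: float = 0.25  # mm between stations
    area_jump: float = 0.30
    end_margin: float = 1.5  # mm skipped at each centerline end

    def validate(self) -> None:
        if self.step <= 0:
            raise ValueError("csa.step must be positive")
        if self.end_margin < 0:
            raise ValueError("csa.end_margin must be >= 0")


@dataclass
class ValidateConfig:
    pullback: str | None = None  # CSV path; None compares against phantom truth
    start_offset: float = 0.0  # mm
    end_trim: float = 0.0  # mm

    def validate(self) -> None:
        pass


@dataclass
class PipelineConfig:
    input_volume: str | None = None  # path; mutually exclusive with phantom
    phantom: dict | None = None  # PhantomSpec keyword arguments
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    centerline: CenterlineConfig = field(default_factory=CenterlineConfig)
    csa: CsaConfig = field(default_factory=CsaConfig)
    validate_cfg: ValidateConfig = field(default_factory=ValidateConfig)
    out_dir: str = "vessel_csa_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("segment", SegmentConfig),
            ("mesh", MeshConfig),
            ("centerline", CenterlineConfig),
            ("csa", CsaConfig),
        ):
            if key in d:
                block = dict(d.pop(key))
                if key == "preprocess" and block.get("bilateral") is not None:
                    block["bilateral"] = tuple(block["bilateral"])
                kwargs[key] = sub(**block)
        if "validate" in d:
            kwargs["validate_cfg"] = ValidateConfig(**dict(d.pop("validate")))
        kwargs.update(d)
        return cls(**kwargs)

    def validated(self) -> "PipelineConfig":
        if (self.input_volume is None) == (self.phantom is None):
            raise ValueError("exactly one of input_volume or phantom must be given")
        if self.phantom is not None:
            block = dict(self.phantom)
            block.setdefault("seed", self.seed)
            PhantomSpec(**_phantom_kwargs(block))  # raises on bad geometry
        for sub in (
            self.preprocess,
            self.segment,
            self.mesh,
            self.centerline,
            self.csa,
            self.validate_cfg,
        ):
            sub.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["validate"] = d.pop("validate_cfg")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_plan(self) -> list[str]:
        plan = ["load-phantom" if self.phantom is not None else "load-volume"]
        plan += ["preprocess", "segment", "mesh", "centerline", "csa"]
        if self.validate_cfg.pullback is not None or self.phantom is not None:
            plan.append("validate")
        return plan


def _phantom_kwargs(block: dict) -> dict:
    block = dict(block)
    for key in ("shape", "spacing", "origin", "profile_params"):
        if key in block:
            block[key] = tuple(block[key])
    if "centerline_params" in block:
        block["centerline_params"] = dict(block["centerline_params"])
    if isinstance(block.get("calcific"), dict):
        from .phantom import CalcificInsert

        block["calcific"] = CalcificInsert(**block["calcific"])
    return block


def _atomic_write(path: str, writer) -> str:
    """Write via a temp file; on failure the partial artifact keeps a .partial suffix.

    The temp name keeps the real extension (format writers sniff it) but is
    only renamed to the final name once the writer succeeds.
    """
    d, base = os.path.split(path)
    tmp = os.path.join(d, "tmp-" + base)
    try:
        writer(tmp)
    except Exception:
        if os.path.exists(tmp):
            os.replace(tmp, path + ".partial")
        raise
    os.replace(tmp, path)
    return path


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute all stages in order; returns artifact paths plus the report dict."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config = config.validated()
    os.makedirs(config.out_dir, exist_ok=True)
    t_start = time.time()
    artifacts: dict[str, str] = {}
    report: dict = {"config_hash": config.config_hash(), "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, str(exc)) from exc
            dt = time.time() - t0
            report["stages"][name] = round(dt, 3)
            log.info("stage %-12s %6.2f s", name, dt)
            return out

        return deco

    truth = None
    if config.phantom is not None:
        block = dict(config.phantom)
        block.setdefault("seed", config.seed)
        spec = PhantomSpec(**_phantom_kwargs(block))

        @stage("load-phantom")
        def volume():
            vol, gt = generate_phantom(spec)
            return vol, gt

        volume, truth = volume
    else:

        @stage("load-volume")
        def volume():
            return read_volume(config.input_volume)

    @stage("preprocess")
    def pre():
        psf = PSFModel(config.preprocess.psf_sigma)
        dec = wiener_deconvolve(volume, psf, config.preprocess.nsr)
        if config.preprocess.selective_threshold is not None:
            dec = selective_deblur(volume, dec, config.preprocess.selective_threshold)
        if config.preprocess.bilateral is not None:
            dec = bilateral_filter(dec, *config.preprocess.bilateral)
        return dec

    @stage("segment")
    def mask():
        seeds = detect_seeds(pre, config.segment.seed_threshold)
        if len(seeds) == 0:
            raise ValueError("no seeds found; lower segment.seed_threshold")
        m = region_grow(pre, seeds, config.segment.grow_params())
        m = largest_component(m)
        if config.segment.calcific_threshold is not None:
            # the >700 HU rule is about physical radiodensity: apply it to the
            # original calibrated volume, not the deconvolved one, where
            # restoration overshoot can spike past any threshold
            m = classify_calcific(volume, m, config.segment.calcific_threshold)
        return m

    artifacts["mask"] = _atomic_write(
        os.path.join(config.out_dir, "lumen_mask.nii.gz"),
        lambda p: write_mask(mask, p),
    )

    @stage("mesh")
    def mesh():
        lumen_only = mask.lumen
        if config.mesh.source == "mask":
            from .volume_io import LabelMask

            src = LabelMask(
                lumen_only.astype(np.uint8), mask.spacing, mask.origin
            )
            m = marching_cubes(src, iso=0.5)
        else:
            dil = ndimage.binary_dilation(
                lumen_only,
                np.ones((3, 3, 3), dtype=bool),
                iterations=config.mesh.mask_dilation,
            )
            inside = float(np.mean(pre.data[lumen_only]))
            shell = dil & ~lumen_only
            outside = float(np.mean(pre.data[shell])) if shell.any() else float(
                pre.data.min()
            )
            iso = config.mesh.iso
            if iso is None:
                iso = 0.5 * (inside + outside)
            hu = np.where(dil, pre.data, min(outside, iso - 1.0)).astype(np.float32)
            m = marching_cubes(Volume(hu, pre.spacing, pre.origin), iso=iso)
        m = curvature_smooth(m, config.mesh.smooth_iterations)
        if m.body_count > 1:  # noise satellites: keep the dominant shell
            m = max(m.split(only_watertight=False), key=lambda x: x.area)
        return m

    artifacts["mesh"] = _atomic_write(
        os.path.join(config.out_dir, "lumen_mesh.obj"),
        lambda p: write_mesh(mesh, p, format="obj"),
    )

    @stage("centerline")
    def centerline():
        from .volume_io import LabelMask

        # calcific carve-out may disconnect slivers; thin the dominant body
        lumen = largest_component(
            LabelMask(mask.lumen.astype(np.uint8), mask.spacing, mask.origin)
        )
        sk = thin_skeleton(lumen)
        path = extract_main_path(sk)
        pts = np.asarray(mask.origin) + np.asarray(path, dtype=float) * np.asarray(
            mask.spacing
        )
        sm = smooth_points(pts, config.centerline.smooth_window)
        return bezier_refine(
            sm, samples_per_segment=config.centerline.samples_per_segment
        )

    def _write_centerline(p):
        import pandas as pd

        pd.DataFrame(
            {
                "s_mm": centerline.arc_lengths,
                "x": centerline.points[:, 0],
                "y": centerline.points[:, 1],
                "z": centerline.points[:, 2],
                "tx": centerline.tangents[:, 0],
                "ty": centerline.tangents[:, 1],
                "tz": centerline.tangents[:, 2],
            }
        ).to_csv(p, index=False, float_format="%.6f")

    artifacts["centerline"] = _atomic_write(
        os.path.join(config.out_dir, "centerline.csv"), _write_centerline
    )

    @stage("csa")
    def profile():
        return build_profile(
            mesh,
            centerline,
            step=config.csa.step,
            area_jump=config.csa.area_jump,
            end_margin=config.csa.end_margin,
        )

    artifacts["profile"] = _atomic_write(
        os.path.join(config.out_dir, "profile.csv"), profile.write_csv
    )

    comparison = None
    if config.validate_cfg.pullback is not None:

        @stage("validate")
        def comparison():
            frames = read_pullback(config.validate_cfg.pullback)
            return align_series(
                profile,
                frames,
                config.validate_cfg.start_offset,
                config.validate_cfg.end_trim,
            )

    elif truth is not None:

        @stage("validate")
        def comparison():
            from scipy.spatial import cKDTree

            from .validation import ComparisonResult

            # align by geometry: each section center projects onto the true
            # centerline, so the skeleton's end retraction cannot shift the
            # stenosis position between the two series
            centers = np.array(
                [sec.center for sec in profile.valid_sections]
            )
            tree = cKDTree(truth.points)
            _, nearest = tree.query(centers)
            s_true = truth.s[nearest]
            ref = truth.csa(s_true)
            return ComparisonResult(
                positions=profile.s, ref=ref, test=profile.areas
            )

    if comparison is not None:
        report["validation"] = comparison.summary()

    report["artifacts"] = artifacts
    report["runtime_s"] = round(time.time() - t_start, 3)
    report["versions"] = _versions()
    report["seed"] = config.seed

    def _write_report(p):
        with open(p, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    artifacts["report"] = _atomic_write(
        os.path.join(config.out_dir, "report.json"), _write_report
    )
    return report


def _versions() -> dict:
    import scipy
    import skimage
    import trimesh as _trimesh

    return {
        "vessel_csa": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "trimesh": _trimesh.__version__,
    }
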