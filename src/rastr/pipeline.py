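"""Pipeline orchestration: simulate → align → average → subtract → pick → dedup.

A run is driven by a single :class:`PipelineConfig` (serializable to YAML)
plus one master seed; each stage derives its own child seed from the
master with a stable hash, so stages are independently reproducible.
Every stage writes its artifacts (MRC stacks/volumes, STAR metadata,
plain-text pick tables) into the run directory together with a
machine-readable ``run_report.json`` summarizing segment and particle
counts per stage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthtube
from .align import AlignConfig, align_stack
from .azimuthal import cylindricity, iterate_alignment, reconstruct, smooth_z
from .formats import (Image2D, ImageStack, read_picks, read_stack, write_picks,
                      write_stack, write_volume)
from .picking import (boxes_for_picks, eliminate_duplicates,
                      pick_stack_by_classification, pick_stack_by_template)
from .subtraction import subtract_stack

__all__ = ["PipelineConfig", "run_pipeline", "report", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31 - 1)


@dataclass
class SimulateConfig:
    enabled: bool = True
    mode: str = "segments"            # "segments" or "micrograph"
    n_segments: int = 20
    image_size: int = 192
    pixel_size: float = 4.32
    outer_radius: float = 137.5
    bilayer_separation: float = 35.0
    shell_sigma: float = 7.0
    particle_sigma: float = 45.0
    particle_amplitude: float = 1.0
    attachment_offset: float = 20.0
    particles_per_segment: int = 4
    snr: float | None = 0.3
    min_axial_spacing_px: float = 30.0
    # micrograph mode
    micrograph_shape: tuple[int, int] = (500, 2000)
    segment_step: int = 64
    n_particles: int = 20
    psi_deg: float = 80.0
    defocus: float | None = None


@dataclass
class AverageConfig:
    size: int = 128
    z_fraction: float = 0.8
    ring_average: bool = True
    refine: bool = False
    max_iter: int = 5


@dataclass
class SubtractOptions:
    mask_frac: float = 0.1
    refine: bool = True
    remove_axial_residual: bool = True


@dataclass
class TemplatePickConfig:
    enabled: bool = True
    threshold: float = 0.2
    min_separation_px: float = 20.0
    n_rotations: int = 1


@dataclass
class ClassifyPickConfig:
    enabled: bool = False
    divisions: tuple[int, int] = (6, 6)
    subbox_size: int = 64
    k: int = 10
    n_iter: int = 12
    rot_step_deg: float = 90.0
    max_shift_px: int = 16
    n_rounds: int = 4


@dataclass
class DedupConfig:
    dist_px: float = 21.0
    ncc_threshold: float = 0.8
    box_size: int = 48


@dataclass
class PipelineConfig:
    seed: int = 0
    input_stack: str | None = None    # used when simulation is disabled
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    average: AverageConfig = field(default_factory=AverageConfig)
    subtract: SubtractOptions = field(default_factory=SubtractOptions)
    template: TemplatePickConfig = field(default_factory=TemplatePickConfig)
    classify: ClassifyPickConfig = field(default_factory=ClassifyPickConfig)
    dedup: DedupConfig = field(default_factory=DedupConfig)
    stages: tuple[str, ...] = ("simulate", "align", "average", "subtract",
                               "pick", "dedup")

    def validate(self) -> None:
        order = ("simulate", "align", "average", "subtract", "pick", "dedup")
        enabled = set(self.stages)
        unknown = enabled - set(order)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        deps = {"average": "align", "subtract": "average", "pick": "subtract",
                "dedup": "pick"}
        for stage, dep in deps.items():
            if stage in enabled and dep not in enabled:
                raise ValueError(f"stage '{stage}' requires stage '{dep}'")
        if "simulate" not in enabled and self.input_stack is None:
            raise ValueError("no input: enable simulation or provide input_stack")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            attr = getattr(cfg, key)
            if hasattr(attr, "__dataclass_fields__") and isinstance(value, dict):
                for k2, v2 in value.items():
                    if not hasattr(attr, k2):
                        raise ValueError(f"unknown config key: {key}.{k2}")
                    if isinstance(v2, list):
                        v2 = tuple(v2)
                    setattr(attr, k2, v2)
            else:
                if isinstance(value, list):
                    value = tuple(value)
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _tube_profile(sim: SimulateConfig) -> synthtube.TubeProfile:
    return synthtube.TubeProfile(sim.outer_radius, sim.bilayer_separation,
                                 sim.shell_sigma)


def _particle_model(sim: SimulateConfig) -> synthtube.ParticleModel:
    return synthtube.ParticleModel.gaussian_blob(
        sigma=sim.particle_sigma, voxel_size=sim.pixel_size,
        amplitude=sim.particle_amplitude, attachment_offset=sim.attachment_offset)


def run_pipeline(config: PipelineConfig, out_dir: str | Path, log=print) -> Path:
    """Execute the enabled stages; returns the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    rep: dict = {"seed": config.seed, "stages": list(config.stages)}
    sim = config.simulate
    profile = _tube_profile(sim)
    particle = _particle_model(sim) if sim.particles_per_segment or sim.n_particles else None

    if "simulate" in config.stages:
        seed = derive_seed(config.seed, "simulate")
        if sim.mode == "micrograph":
            _, stack, truth = synthtube.simulate_micrograph(
                tuple(sim.micrograph_shape), sim.image_size, sim.segment_step,
                sim.pixel_size, profile=profile, particle=particle,
                n_particles=sim.n_particles, psi_deg=sim.psi_deg, snr=sim.snr,
                min_axial_spacing_px=sim.min_axial_spacing_px, seed=seed)
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            rep["n_true_particles"] = int(len(truth))
        else:
            stack, truths = synthtube.simulate_segments(
                sim.n_segments, sim.image_size, sim.pixel_size, profile=profile,
                particle=particle if sim.particles_per_segment else None,
                particles_per_segment=sim.particles_per_segment, snr=sim.snr,
                min_axial_spacing_px=sim.min_axial_spacing_px,
                defocus=sim.defocus, seed=seed)
            rows = [{"segment_id": i, "local_x": x, "local_y": y}
                    for i, t in enumerate(truths) for x, y in t.particle_xy_px]
            import pandas as pd
            pd.DataFrame(rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            rep["n_true_particles"] = sum(len(t.particle_xy_px) for t in truths)
        write_stack(stack, out / "segments.mrc")
        rep["n_segments"] = len(stack)
        log(f"simulate: {len(stack)} segments")
    else:
        stack = read_stack(config.input_stack)
        rep["n_segments"] = len(stack)

    if "align" in config.stages:
        config.align.seed = derive_seed(config.seed, "align")
        stack = align_stack(stack, config.align)
        n_ok = int(stack.metadata["align_ok"].sum())
        rep["n_aligned"] = n_ok
        write_stack(stack, out / "aligned.mrc")
        log(f"align: {n_ok}/{len(stack)} segments aligned")

    avg = None
    if "average" in config.stages:
        av = config.average
        if av.refine:
            stack, avg, history = iterate_alignment(
                stack, av.size, av.z_fraction, av.max_iter)
            rep["refine_history"] = history
        raw = reconstruct(stack, av.size)
        rep["cylindricity"] = float(cylindricity(smooth_z(raw, av.z_fraction)))
        avg = smooth_z(reconstruct(stack, av.size,
                                   ring_average=av.ring_average), av.z_fraction) \
            if av.ring_average else smooth_z(raw, av.z_fraction)
        rep["n_in_average"] = int(avg.n_segments)
        write_volume(avg.volume, out / "azimuthal_average.mrc")
        log(f"average: {avg.n_segments} segments, cylindricity {rep['cylindricity']:.4f}")

    if "subtract" in config.stages:
        sc = config.subtract
        stack = subtract_stack(stack, avg, sc.mask_frac, refine=sc.refine,
                               remove_axial_residual=sc.remove_axial_residual)
        rep["n_subtracted"] = int(stack.metadata["subtract_ok"].sum())
        rep["mean_alpha"] = float(np.nanmean(stack.metadata["scale_alpha"]))
        rep["mean_residual_rms"] = float(np.nanmean(stack.metadata["residual_rms"]))
        write_stack(stack, out / "subtracted.mrc")
        log(f"subtract: {rep['n_subtracted']} segments, mean alpha {rep['mean_alpha']:.3f}")

    picks = None
    if "pick" in config.stages:
        import pandas as pd
        frames = []
        if config.template.enabled:
            tc = config.template
            template = Image2D(
                particle.density.voxels.sum(axis=0) * sim.pixel_size, sim.pixel_size)
            tp = pick_stack_by_template(stack, template, tc.threshold,
                                        tc.min_separation_px, tc.n_rotations)
            tp["method"] = "template"
            frames.append(tp)
            rep["n_template_picks"] = int(len(tp))
            log(f"pick-template: {len(tp)} picks")
        if config.classify.enabled:
            cc = config.classify
            cp, _ = pick_stack_by_classification(
                stack, tuple(cc.divisions), cc.subbox_size, k=cc.k,
                n_iter=cc.n_iter, seed=derive_seed(config.seed, "classify"),
                rot_step_deg=cc.rot_step_deg, max_shift_px=cc.max_shift_px,
                n_rounds=cc.n_rounds)
            cp["method"] = "classification"
            frames.append(cp)
            rep["n_classification_picks"] = int(len(cp))
            log(f"pick-classify: {len(cp)} picks")
        if not frames:
            raise ValueError("pick stage enabled but both pickers disabled")
        picks = pd.concat(frames, ignore_index=True)
        write_picks(picks, out / "picks.tsv")
        rep["n_picks"] = int(len(picks))

    if "dedup" in config.stages:
        dc = config.dedup
        boxes = boxes_for_picks(stack, picks, dc.box_size)
        unique = eliminate_duplicates(picks, boxes, dc.dist_px, dc.ncc_threshold)
        write_picks(unique, out / "picks_unique.tsv")
        rep["n_picks_after_dedup"] = int(len(unique))
        log(f"dedup: {len(picks)} -> {len(unique)} picks")

    with open(out / "run_report.json", "w") as fh:
        json.dump(rep, fh, indent=2)
    return out


def report(run_dir: str | Path) -> dict:
    """Summarize a (possibly partial) run from its report file."""
    run_dir = Path(run_dir)
    path = run_dir / "run_report.json"
    if not path.exists():
        raise FileNotFoundError(f"no run report in {run_dir}")
    with open(path) as fh:
        rep = json.load(fh)
    if "n_picks" in rep and "n_picks_after_dedup" in rep:
        assert rep["n_picks_after_dedup"] <= rep["n_picks"]
    return rep
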