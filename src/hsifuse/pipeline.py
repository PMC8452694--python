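"""End-to-end orchestration: preprocess -> congruence -> multiset -> unmixing.

The pipeline mirrors the standard image-fusion workflow: per-platform
spectral cleanup, resampling of every image to the coarsest (reference)
pixel grid, contour-based rigid alignment against the reference platform,
restriction to the jointly scanned area, 2-norm block balancing, multiset
assembly and constrained MCR-ALS.  Every stage writes its outputs under a
numbered directory inside ``output_dir`` so a run can be resumed from any
stage (``resume_from``) or stopped early (``stop_after``), and the stage
products can be inspected individually.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import congruence as cg
from . import preprocessing as pp
from .io import HSICube, load_cube, save_cube, unfold
from .mcr import ConstraintSet, MCRResult, component_maps, run_mcr_als
from .multiset import Multiset, assemble, balance

STAGES = ["preprocess", "resample", "align", "fuse", "unmix", "report"]

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a remediation hint."""


@dataclass
class RunConfig:
    """Declarative description of one fusion run."""

    inputs: list[dict] = field(default_factory=list)  # {path, format}
    output_dir: str = "hsifuse_out"
    reference: str = "ftir"
    plans: dict[str, pp.PreprocessPlan] = field(default_factory=dict)
    balance_kind: str = "frobenius"
    n_components: int = 2
    init: str = "simplisma"
    constraints: ConstraintSet | None = None
    tol_pct: float = 0.1
    max_iter: int = 50
    noise_alpha: float = 5.0
    align_options: dict = field(default_factory=dict)
    seed: int = 0


def _plan_from_dict(d: dict) -> pp.PreprocessPlan:
    kw: dict = {}
    if "saturation_value" in d:
        kw["saturation_value"] = float(d["saturation_value"])
    if "spectral_ranges" in d:
        kw["spectral_ranges"] = [tuple(map(float, r)) for r in d["spectral_ranges"]]
    if "bin_factor" in d:
        kw["bin_factor"] = int(d["bin_factor"])
    if "bin_stat" in d:
        kw["bin_stat"] = d["bin_stat"]
    if "spike_zmax" in d:
        kw["spike_zmax"] = float(d["spike_zmax"])
    if "asls" in d:
        a = d["asls"]
        kw["asls_enabled"] = True
        kw["asls_lambda"] = float(a.get("lambda", 1e5))
        kw["asls_p"] = float(a.get("p", 0.001))
        kw["asls_iters"] = int(a.get("iters", 10))
    if "sg" in d:
        g = d["sg"]
        kw["sg_window"] = int(g.get("window", 9))
        kw["sg_polyorder"] = int(g.get("polyorder", 3))
        kw["sg_deriv_order"] = int(g.get("deriv", 2))
    return pp.PreprocessPlan(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    plans = {
        mod: _plan_from_dict(d) for mod, d in (raw.get("preprocess") or {}).items()
    }
    constraints = None
    if raw.get("constraints"):
        constraints = ConstraintSet.from_dict(raw["constraints"])
    return RunConfig(
        inputs=raw.get("inputs", []),
        output_dir=raw.get("output_dir", "hsifuse_out"),
        reference=raw.get("reference", "ftir"),
        plans=plans,
        balance_kind=raw.get("balance", "frobenius"),
        n_components=int(raw.get("n_components", 2)),
        init=raw.get("init", "simplisma"),
        constraints=constraints,
        tol_pct=float(raw.get("tol_pct", 0.1)),
        max_iter=int(raw.get("max_iter", 50)),
        noise_alpha=float(raw.get("noise_alpha", 5.0)),
        align_options=raw.get("align", {}) or {},
        seed=int(raw.get("seed", 0)),
    )


def _cropped_axis(axis: np.ndarray, plan: pp.PreprocessPlan | None) -> np.ndarray:
    if plan is None or not plan.spectral_ranges:
        return axis
    keep = np.zeros(axis.size, dtype=bool)
    for lo, hi in plan.spectral_ranges:
        lo, hi = (lo, hi) if lo <= hi else (hi, lo)
        keep |= (axis >= lo) & (axis <= hi)
    return axis[keep]


def validate_config(config: RunConfig, axes: dict[str, np.ndarray]) -> None:
    """Cheap validation pass before any heavy compute.

    Checks that input files exist and that every spectral zero-range in
    the constraint set intersects the (post-crop) axis of its platform.
    """
    for entry in config.inputs:
        p = Path(entry["path"])
        if not p.exists():
            raise PipelineError(f"validate: input file {p} does not exist")
    if config.reference not in axes:
        raise PipelineError(
            f"validate: reference modality {config.reference!r} not among inputs"
        )
    if config.constraints is not None:
        eff = {m: _cropped_axis(ax, config.plans.get(m)) for m, ax in axes.items()}
        layout_rows = {"_probe": (0, 1)}
        c = 0
        col_blocks = {}
        for m, ax in eff.items():
            col_blocks[m] = (c, c + ax.size)
            c += ax.size
        try:
            config.constraints.materialize(layout_rows, col_blocks, eff, (1, c))
        except ValueError as exc:
            raise PipelineError(f"validate: bad constraint set: {exc}") from exc


# ---------------------------------------------------------------------------
# Stage I/O helpers
# ---------------------------------------------------------------------------


def _stage_dir(out: Path, stage: str) -> Path:
    d = out / f"{STAGES.index(stage):02d}_{stage}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _save_cubes(cubes: dict[tuple[str, str], HSICube], d: Path) -> None:
    for (sid, mod), cube in cubes.items():
        save_cube(cube, d / f"{sid}_{mod}.h5", "hdf5")


def _load_cubes(d: Path) -> dict[tuple[str, str], HSICube]:
    cubes = {}
    for p in sorted(d.glob("*.h5")):
        cube = load_cube(p, "hdf5")
        cubes[(cube.sample_id, cube.modality)] = cube
    if not cubes:
        raise PipelineError(f"resume: no cubes found under {d}")
    return cubes


def save_result(result: MCRResult, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("C", data=result.C)
        f.create_dataset("St", data=result.St)
        f.create_dataset("lof_trace", data=np.asarray(result.lof_trace))
        f.attrs["lof_final"] = result.lof_final
        f.attrs["r2"] = result.r2
        f.attrs["n_iter"] = result.n_iter
        f.attrs["converged"] = result.converged
        if result.constraint_echo is not None:
            f.attrs["constraints"] = json.dumps(result.constraint_echo.to_dict())


def load_result(path: str | Path) -> MCRResult:
    with h5py.File(path, "r") as f:
        echo = None
        if "constraints" in f.attrs:
            echo = ConstraintSet.from_dict(json.loads(f.attrs["constraints"]))
        return MCRResult(
            C=f["C"][()],
            St=f["St"][()],
            lof_trace=list(f["lof_trace"][()]),
            lof_final=float(f.attrs["lof_final"]),
            r2=float(f.attrs["r2"]),
            n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]),
            constraint_echo=echo,
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_preprocess(cubes, config: RunConfig):
    out = {}
    for key, cube in cubes.items():
        plan = config.plans.get(cube.modality)
        out[key] = pp.apply_plan(cube, plan) if plan is not None else cube
    return out


def _stage_resample(cubes, config: RunConfig):
    ref_pix = max(c.pixel_size for c in cubes.values())
    for key, cube in cubes.items():
        if cube.modality == config.reference:
            ref_pix = cube.pixel_size
            break
    out = {}
    for key, cube in cubes.items():
        out[key] = (
            cube if abs(cube.pixel_size - ref_pix) < 1e-9
            else pp.resample_to_grid(cube, ref_pix)
        )
    return out


def _stage_align(cubes, config: RunConfig, out_dir: Path):
    opts = dict(config.align_options)
    method = opts.pop("binarize", "otsu-sqrt")
    fraction = float(opts.pop("fraction", 0.5))
    theta_grid = tuple(opts.pop("theta_grid", (-10.0, -5.0, 0.0, 5.0, 10.0)))
    min_overlap = float(opts.pop("min_overlap", 0.5))
    samples = sorted({sid for sid, _ in cubes})
    out = {}
    transforms = {}
    for sid in samples:
        ref_key = (sid, config.reference)
        if ref_key not in cubes:
            raise PipelineError(
                f"align: sample {sid!r} has no {config.reference!r} reference cube"
            )
        ref_cube = cubes[ref_key]
        ref_map = cg.binarize(
            cg.intensity_map(ref_cube), method, fraction, ref_cube.pixel_size
        )
        out[ref_key] = ref_cube
        transforms[f"{sid}_{config.reference}"] = cg.RigidTransform()
        for (s, mod), cube in cubes.items():
            if s != sid or mod == config.reference:
                continue
            mov_map = cg.binarize(
                cg.intensity_map(cube), method, fraction, cube.pixel_size
            )
            t = cg.align(
                ref_map, mov_map, theta_grid=theta_grid, min_overlap=min_overlap
            )
            out[(s, mod)] = cg.apply_transform(
                cube, t, out_shape=ref_cube.data.shape[:2]
            )
            transforms[f"{s}_{mod}"] = t
    (out_dir / "transforms.json").write_text(
        json.dumps(
            {
                k: {"dx": t.dx, "dy": t.dy, "theta_deg": t.theta}
                for k, t in transforms.items()
            },
            indent=1,
        )
    )
    return out


def _stage_fuse(cubes, config: RunConfig) -> Multiset:
    samples = sorted({sid for sid, _ in cubes})
    modalities = [config.reference] + sorted(
        {m for _, m in cubes} - {config.reference}
    )
    blocks = {}
    for sid in samples:
        group = [cubes[(sid, m)] for m in modalities]
        mask = cg.common_support(group)
        for m, cube in zip(modalities, group):
            blocks[(sid, m)] = unfold(cube.copy(valid_mask=mask))
    balanced = dict(
        zip(blocks.keys(), balance(list(blocks.values()), config.balance_kind))
    )
    return assemble(balanced)


def _stage_unmix(mset: Multiset, config: RunConfig) -> MCRResult:
    return run_mcr_als(
        mset,
        n_components=config.n_components,
        init=config.init,
        constraints=config.constraints,
        tol_pct=config.tol_pct,
        max_iter=config.max_iter,
        noise_alpha=config.noise_alpha,
    )


def _stage_report(result: MCRResult, mset: Multiset, config: RunConfig, d: Path):
    import tifffile

    for mod in mset.modalities:
        cols = mset.col_slice(mod)
        df = pd.DataFrame(
            result.St[:, cols].T,
            columns=[f"component_{k}" for k in range(result.St.shape[0])],
        )
        df.insert(0, "axis", mset.axes[mod])
        df.to_csv(d / f"spectra_{mod}.csv", index=False)
    for sid in mset.samples:
        maps = component_maps(result, mset, sid, fill=0.0)
        tifffile.imwrite(
            d / f"maps_{sid}.tif", maps.astype(np.float32), photometric="minisblack"
        )
    lines = [
        f"components: {result.C.shape[1]}",
        f"iterations: {result.n_iter} (converged: {result.converged})",
        f"lof_final_pct: {result.lof_final:.4f}",
        f"r2: {result.r2:.6f}",
        "lof_trace: " + ", ".join(f"{v:.4f}" for v in result.lof_trace),
        "blocks: "
        + "; ".join(
            f"{sid} x {mod}: rows {mset.row_blocks[sid]}, cols {mset.col_blocks[mod]}, "
            f"weight {mset.weights[(sid, mod)]:.4g}"
            for sid in mset.samples
            for mod in mset.modalities
        ),
    ]
    (d / "run_log.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: RunConfig,
    cubes: dict[tuple[str, str], HSICube] | None = None,
    resume_from: str | None = None,
    stop_after: str | None = None,
) -> MCRResult | None:
    """Execute the fusion workflow, persisting every stage's outputs.

    ``cubes`` may be passed directly (e.g. straight from the phantom
    generator); otherwise they are loaded from ``config.inputs``.
    ``resume_from`` restarts at a later stage using the artifacts already
    on disk; ``stop_after`` halts once the named stage has run.  Returns
    the :class:`~hsifuse.mcr.MCRResult` (or ``None`` when stopped before
    the unmix stage).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = STAGES.index(resume_from) if resume_from else 0
    stop = STAGES.index(stop_after) if stop_after else len(STAGES) - 1
    if start > stop:
        raise PipelineError("resume_from is after stop_after")
    t0 = time.time()

    if cubes is None and start == 0:
        cubes = {}
        for entry in config.inputs:
            cube = load_cube(entry["path"], entry.get("format", "hdf5"))
            cubes[(cube.sample_id, cube.modality)] = cube
        if not cubes:
            raise PipelineError("no input cubes; list them under 'inputs'")
    if start == 0 and cubes:
        validate_config(config, {c.modality: c.axis for c in cubes.values()})

    mset: Multiset | None = None
    result: MCRResult | None = None
    for idx in range(start, stop + 1):
        stage = STAGES[idx]
        d = _stage_dir(out, stage)
        try:
            if stage == "preprocess":
                cubes = _stage_preprocess(cubes, config)
                _save_cubes(cubes, d)
            elif stage == "resample":
                if cubes is None:
                    cubes = _load_cubes(_stage_dir(out, "preprocess"))
                cubes = _stage_resample(cubes, config)
                _save_cubes(cubes, d)
            elif stage == "align":
                if cubes is None:
                    cubes = _load_cubes(_stage_dir(out, "resample"))
                cubes = _stage_align(cubes, config, d)
                _save_cubes(cubes, d)
            elif stage == "fuse":
                if cubes is None:
                    cubes = _load_cubes(_stage_dir(out, "align"))
                mset = _stage_fuse(cubes, config)
                mset.save(d / "multiset.h5")
            elif stage == "unmix":
                if mset is None:
                    mset = Multiset.load(_stage_dir(out, "fuse") / "multiset.h5")
                result = _stage_unmix(mset, config)
                save_result(result, d / "result.h5")
            elif stage == "report":
                if mset is None:
                    mset = Multiset.load(_stage_dir(out, "fuse") / "multiset.h5")
                if result is None:
                    result = load_result(_stage_dir(out, "unmix") / "result.h5")
                _stage_report(result, mset, config, d)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage {stage!r} failed: {exc} "
                f"(inspect {d} and rerun with resume_from={stage!r})"
            ) from exc
    (out / "elapsed.txt").write_text(f"{time.time() - t0:.2f} s\n")
    return result
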