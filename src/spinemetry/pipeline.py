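"""Configuration, file I/O and the end-to-end synthetic experiment.

``run_full_synthetic_experiment`` reproduces the structure of the
imaging comparison: two groups of spines are sampled from their
morphological presets, rendered as STED-like stacks, measured blind to
the ground truth, converted to compartmentalization factors, and
compared (normality-gated two-group tests plus KS with the first group
as reference, on spine density, spine length, head width, neck length,
neck width and cf).

Every output table carries the configuration hash in a leading comment
line; a single top-level seed is fanned out to per-stage child seeds
through ``numpy.random.SeedSequence`` spawning, so stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import compartmentalization as comp
from . import morphometry as morpho
from . import stats as st
from . import synthetic as syn

__all__ = [
    "PipelineConfig",
    "ExperimentResult",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "single_spine_annotation",
    "annotation_to_pixel_table",
    "run_full_synthetic_experiment",
]

log = logging.getLogger("spinemetry")

MORPH_FEATURES = ("spine_length", "head_width", "neck_length", "neck_width", "cf")


class FormatError(ValueError):
    """A file is malformed; the message names the offending field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs; YAML round-trips losslessly."""

    seed: int = 0
    n_spines_per_group: int = 250
    n_branches: int = 8
    alpha: float = 0.05
    diffusion_coefficient: float = comp.DEFAULT_D
    imaging: syn.ImagingConfig = field(default_factory=syn.ImagingConfig)
    groups: dict[str, syn.GroupMorphParams] = field(default_factory=lambda: {
        "wt": syn.WT_PRESET, "APP/PS1": syn.APPPS1_PRESET})
    morphometry: morpho.MorphometryConfig = field(
        default_factory=morpho.MorphometryConfig)
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "imaging" in d and isinstance(d["imaging"], dict):
            d["imaging"] = syn.ImagingConfig(**d["imaging"])
        if "groups" in d:
            d["groups"] = {k: syn.GroupMorphParams(**v) if isinstance(v, dict)
                           else v for k, v in d["groups"].items()}
        if "morphometry" in d and isinstance(d["morphometry"], dict):
            d["morphometry"] = morpho.MorphometryConfig(**d["morphometry"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# stack / table I/O
# ---------------------------------------------------------------------------

def write_stack(stack: syn.ImageStack, path, config_hash: str | None = None) -> None:
    """Multi-page TIFF (one page per z) plus a JSON metadata sidecar."""
    path = Path(path)
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating) and np.allclose(data, np.round(data)):
        data = np.round(data).astype(np.uint32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "provenance": stack.provenance,
    }
    if config_hash:
        meta["config_hash"] = config_hash
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path) -> syn.ImageStack:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("pixel_size_xy_um", "z_step_um"):
        if key not in meta:
            raise FormatError(f"metadata sidecar lacks required field {key!r}")
    vox = tifffile.imread(path)
    if vox.ndim == 2:
        vox = vox[None, ...]
    return syn.ImageStack(voxels=vox, pixel_size_xy=float(meta["pixel_size_xy_um"]),
                          z_step=float(meta["z_step_um"]),
                          provenance=str(meta.get("provenance", "")))


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """CSV with a leading ``# config_hash`` comment (skipped on read)."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Tolerant CSV reader: comments skipped, extra columns preserved."""
    try:
        return pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"unreadable table {Path(path).name}: {exc}") from exc


# ---------------------------------------------------------------------------
# per-spine rendering helpers
# ---------------------------------------------------------------------------

def single_spine_annotation(rec: syn.SpineRecord, dendrite_radius: float,
                            half_width: float = 0.8) -> syn.GroundTruthAnnotation:
    """Crop one spine (plus its local dendrite segment) into a patch
    annotation with its own origin, for patch-wise rendering."""
    g = rec.geometry
    x0 = float(g.attachment_point[0])
    shift = np.array([x0 - half_width, 0.0, 0.0])
    geom = syn.SpineGeometry(
        attachment_point=g.attachment_point - shift,
        path=g.path - shift[None, :],
        head_width=g.head_width, neck_length=g.neck_length,
        neck_width=g.neck_width, spine_length=g.spine_length)
    new_rec = syn.SpineRecord(
        spine_id=rec.spine_id, geometry=geom,
        seed_point_um=rec.seed_point_um - shift[:2],
        head_hint_um=rec.head_hint_um - shift[:2])
    dend = np.array([[0.0, 0.0, 0.0], [2 * half_width, 0.0, 0.0]])
    return syn.GroundTruthAnnotation(
        spines=[new_rec], dendrite_path=dend, dendrite_length=2 * half_width,
        dendrite_radius=dendrite_radius)


def annotation_to_pixel_table(ann: syn.GroundTruthAnnotation,
                              imaging: syn.ImagingConfig,
                              margin: float = 0.45) -> pd.DataFrame:
    """Seed/hint pixel coordinates in the frame of the rendered stack."""
    y_shift, _ = syn.shifted_annotation_offsets(ann, imaging, margin)
    px = imaging.pixel_size_xy
    rows = []
    for rec in ann.spines:
        g = rec.geometry
        rows.append({
            "spine_id": rec.spine_id,
            "seed_x_px": int((rec.seed_point_um[0]) / px),
            "seed_y_px": int((rec.seed_point_um[1] + y_shift) / px),
            "hint_x_px": int((rec.head_hint_um[0]) / px),
            "hint_y_px": int((rec.head_hint_um[1] + y_shift) / px),
            "true_spine_length": g.spine_length,
            "true_neck_length": g.neck_length,
            "true_neck_width": g.neck_width,
            "true_head_width": g.head_width,
        })
    return pd.DataFrame(rows)


def measure_annotation(stack: syn.ImageStack, pixel_table: pd.DataFrame,
                       config: morpho.MorphometryConfig) -> pd.DataFrame:
    """Measure every annotated spine on a stack's lateral projection."""
    image, px = morpho.project_stack(stack)
    rows = []
    for rec in pixel_table.itertuples(index=False):
        m = morpho.measure_spine(
            image, px, (rec.seed_x_px, rec.seed_y_px),
            (rec.hint_x_px, rec.hint_y_px),
            spine_id=str(rec.spine_id), config=config)
        row = m.to_row()
        log.debug("spine %s flags=%s", m.spine_id, row["flags"] or "-")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    per_spine: pd.DataFrame
    density: pd.DataFrame
    tests: dict[str, dict]
    config_hash: str
    output_dir: Path | None = None


def _measure_group(label: str, params: syn.GroupMorphParams, cfg: PipelineConfig,
                   seed: np.random.SeedSequence) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = cfg.n_spines_per_group
    dendrite_length = n / params.spine_density * 10.0
    pop_seed, render_seed = seed.spawn(2)
    geoms, ann = syn.sample_spine_population(params, n, dendrite_length, pop_seed)

    # branch-wise density: equal partitions of the dendrite
    edges = np.linspace(0.0, dendrite_length, cfg.n_branches + 1)
    xs = np.array([g.attachment_point[0] for g in geoms])
    counts, _ = np.histogram(xs, bins=edges)
    branch_len = dendrite_length / cfg.n_branches
    density_df = pd.DataFrame({
        "group": label,
        "branch": np.arange(cfg.n_branches),
        "branch_length_um": branch_len,
        "n_spines": counts,
        "density_per_10um": [morpho.spine_density(int(c), branch_len)
                             for c in counts],
    })

    spine_seeds = render_seed.spawn(len(ann.spines))
    rows = []
    for rec, s in zip(ann.spines, spine_seeds):
        patch = single_spine_annotation(rec, ann.dendrite_radius)
        stack = syn.render_stack(patch, cfg.imaging, s)
        ptable = annotation_to_pixel_table(patch, cfg.imaging)
        meas = measure_annotation(stack, ptable, cfg.morphometry)
        row = {**ptable.iloc[0].to_dict(), **meas.iloc[0].to_dict()}
        row["group"] = label
        g = rec.geometry
        row["true_cf"] = comp.CompartmentalizationResult.from_widths(
            g.head_width, g.neck_length, g.neck_width).cf
        ok = (row["head_width"] and row["neck_length"] and row["neck_width"]
              and not any(pd.isna([row["head_width"], row["neck_length"],
                                   row["neck_width"]])))
        if ok:
            row["cf"] = comp.CompartmentalizationResult.from_widths(
                row["head_width"], row["neck_length"], row["neck_width"]).cf
        else:
            row["cf"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows), density_df


def run_full_synthetic_experiment(
    config: PipelineConfig,
    output_dir: str | Path | None = None,
) -> ExperimentResult:
    """Sample, render, measure and compare two (or more) groups.

    Statistics compare every later group against the first (reference)
    group: a normality-gated two-group test and a KS test per feature
    (density at branch level, the four morphological features and cf at
    spine level, measured values).
    """
    out = Path(output_dir or config.output_dir) if (output_dir
                                                    or config.output_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    top = np.random.SeedSequence(config.seed)
    group_seeds = top.spawn(len(config.groups))

    per_spine = []
    density = []
    for (label, params), gseed in zip(config.groups.items(), group_seeds):
        log.info("group %s: sampling and measuring %d spines",
                 label, config.n_spines_per_group)
        ps, dens = _measure_group(label, params, config, gseed)
        per_spine.append(ps)
        density.append(dens)
    per_spine = pd.concat(per_spine, ignore_index=True)
    density = pd.concat(density, ignore_index=True)

    labels = list(config.groups)
    ref = labels[0]
    tests: dict[str, dict] = {}
    for other in labels[1:]:
        pair = f"{ref}_vs_{other}" if len(labels) > 2 else ""
        for feat in MORPH_FEATURES:
            a = per_spine.loc[per_spine.group == ref, feat].dropna().to_numpy()
            b = per_spine.loc[per_spine.group == other, feat].dropna().to_numpy()
            key = f"{pair}{feat}" if not pair else f"{pair}_{feat}"
            tests[key] = {
                "group_test": dataclasses.asdict(
                    st.compare_two_groups(a, b, config.alpha)),
                "ks": dataclasses.asdict(st.ks_two_sample(a, b,
                                                          alpha=config.alpha)),
                "mean_ref": float(np.mean(a)), "mean_other": float(np.mean(b)),
            }
        a = density.loc[density.group == ref, "density_per_10um"].to_numpy()
        b = density.loc[density.group == other, "density_per_10um"].to_numpy()
        key = f"{pair}density" if not pair else f"{pair}_density"
        tests[key] = {
            "group_test": dataclasses.asdict(
                st.compare_two_groups(a, b, config.alpha)),
            "ks": dataclasses.asdict(st.ks_two_sample(a, b, alpha=config.alpha)),
            "mean_ref": float(np.mean(a)), "mean_other": float(np.mean(b)),
        }

    result = ExperimentResult(per_spine=per_spine, density=density, tests=tests,
                              config_hash=config.config_hash, output_dir=out)
    if out:
        write_table(per_spine, out / "morphometry.csv", config.config_hash)
        write_table(density, out / "density.csv", config.config_hash)
        (out / "stats.json").write_text(json.dumps(
            {"config_hash": config.config_hash, "tests": tests}, indent=1))
        config.to_yaml(out / "config.yaml")
        flags = per_spine["flags"].astype(str)
        log.info("run complete: %d spines, %d flagged",
                 len(per_spine), int((flags != "").sum()))
    return result
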