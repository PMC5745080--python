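"""End-to-end workflows: configuration, logging, and stage wiring.

A :class:`RunConfig`-style mapping (typically loaded from YAML) selects
one of four workflows and carries every parameter of the run:

* ``simulate`` — generate a batch of gradient or in situ phantoms with
  ground-truth sidecars and a manifest CSV;
* ``gradient-profile`` — images -> axis profiles -> ratio -> group
  mean +/- SEM (with optional plot);
* ``angular-extent`` — images -> stain mask -> radial sums -> extent
  table (with white-on-dark visualizations);
* ``compare`` — two-sided homoscedastic t-test between two groups of a
  measurement column.

All outputs are deterministic given the same config and seed, and every
output table carries the seed and a config hash in its header comment.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import angular, axisprofile, groupstats, io_utils, phantom

__all__ = [
    "load_config",
    "run_workflow",
    "simulate_gradient_batch",
    "simulate_insitu_batch",
    "gradient_profile_groups",
    "extent_table",
    "compare_groups",
    "rule_from_config",
    "plot_group_profiles",
]

log = logging.getLogger("embryoquant")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "workflow" not in config:
        raise ValueError("config must be a mapping with a 'workflow' key")
    return config


def rule_from_config(section: dict | None) -> angular.ThresholdRule:
    """Build a ThresholdRule from a config section (default: purple stain)."""
    if not section:
        return angular.default_purple_rule()
    if "background_cutoff" in section and "linear_scores" not in section:
        return angular.default_purple_rule(float(section["background_cutoff"]))
    bounds = section.get("channel_bounds")
    if bounds is not None:
        bounds = {k: tuple(v) for k, v in bounds.items()}
    scores = tuple(tuple(s) for s in section.get("linear_scores", ()))
    return angular.ThresholdRule(channel_bounds=bounds, linear_scores=scores)


# ---------------------------------------------------------------------------
# simulation batches


def simulate_gradient_batch(
    n: int,
    ratio_function,
    image_height: int = 300,
    image_width: int = 700,
    embryo_bbox: tuple[int, int, int, int] | None = None,
    nuclear_level: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` gradient phantoms with per-embryo derived seeds."""
    if embryo_bbox is None:
        embryo_bbox = (50, 25, axisprofile.DEFAULT_ROI_HEIGHT, axisprofile.DEFAULT_ROI_WIDTH)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for s in seeds:
        spec = phantom.GradientPhantomSpec(
            image_height=image_height,
            image_width=image_width,
            embryo_bbox=embryo_bbox,
            ratio_function=ratio_function,
            nuclear_level=nuclear_level,
            noise_sigma=noise_sigma,
            seed=int(s),
        )
        out.append(phantom.generate_gradient_phantom(spec))
    return out


def default_embryo_ellipse(image_height: int, image_width: int, margin: float = 30.0) -> angular.EllipseROI:
    """Centered axis-aligned embryo ellipse filling the image minus a margin."""
    return angular.EllipseROI(
        center=(image_height / 2, image_width / 2),
        semi_axis_a=image_width / 2 - margin,
        semi_axis_b=image_height / 2 - margin,
    )


def simulate_insitu_batch(
    extents: np.ndarray,
    image_height: int = 420,
    image_width: int = 520,
    ellipse: angular.EllipseROI | None = None,
    sector_center: float = 270.0,
    stain_band_depth: float = 35.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    snap_to_bins: int | None = 360,
) -> list[tuple[np.ndarray, float]]:
    """Generate one in situ phantom per requested extent fraction.

    The stained sector is centered on ``sector_center`` (the ventral
    margin in the emulated images) so a batch of varying extents shares
    a common domain midpoint.  With ``snap_to_bins`` (default 360) the
    sector is realized at the angular resolution of the downstream
    measurement: the span is rounded to a whole number of bins and the
    sector edges are placed on half-bin offsets, midway between bin
    centers.  The ground truth returned with each phantom is the
    realized sector's extent, so recovered and true extents are directly
    comparable at bin resolution.  The default geometry keeps the
    stained rim at radii large enough that nearest-pixel ray sampling
    resolves the half-bin gap between a sector edge and the adjacent
    bin center.
    """
    if ellipse is None:
        ellipse = default_embryo_ellipse(image_height, image_width)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(extents))
    out = []
    for extent, s in zip(extents, seeds):
        span = 360.0 * float(np.clip(extent, 0.0, 1.0))
        if snap_to_bins:
            deg_per_bin = 360.0 / snap_to_bins
            span = deg_per_bin * round(span / deg_per_bin)
            start = (
                (np.floor((sector_center - span / 2.0) / deg_per_bin) + 0.5) * deg_per_bin
            ) % 360.0
        else:
            start = (sector_center - span / 2.0) % 360.0
        end = start + span
        if end > 360.0:
            end -= 360.0
        if span >= 360.0:
            start, end = 0.0, 360.0
        spec = phantom.InSituPhantomSpec(
            image_height=image_height,
            image_width=image_width,
            ellipse=ellipse,
            stain_sector=(start, end),
            stain_band_depth=stain_band_depth,
            noise_sigma=noise_sigma,
            seed=int(s),
        )
        out.append(phantom.generate_insitu_phantom(spec))
    return out


# ---------------------------------------------------------------------------
# analysis pipelines


def gradient_profile_groups(
    images_by_group: dict[str, list[np.ndarray]],
    roi: axisprofile.RectROI,
    target_bins: int = 100,
    ventral_first: bool | dict[str, list[bool]] = True,
    nuclear_floor: float | None = None,
) -> tuple[dict[str, list[axisprofile.AxisProfile]], dict[str, axisprofile.GroupProfile]]:
    """Per-group profile extraction, alignment, ratio and aggregation."""
    profiles: dict[str, list[axisprofile.AxisProfile]] = {}
    groups: dict[str, axisprofile.GroupProfile] = {}
    for group, images in images_by_group.items():
        t0 = time.perf_counter()
        raw = [axisprofile.extract_axis_profile(img, roi) for img in images]
        flags = ventral_first if isinstance(ventral_first, bool) else ventral_first[group]
        aligned = axisprofile.normalize_and_align(raw, target_bins=target_bins, ventral_first=flags)
        with_ratio = [axisprofile.ratio_profile(p, nuclear_floor) for p in aligned]
        profiles[group] = with_ratio
        groups[group] = axisprofile.aggregate_group(with_ratio)
        log.info(
            "gradient-profile group=%s n=%d bins=%d (%.2fs)",
            group, len(images), target_bins, time.perf_counter() - t0,
        )
    return profiles, groups


def extent_table(
    images: list[np.ndarray],
    ellipses: list[angular.EllipseROI],
    groups: list[str],
    rule: angular.ThresholdRule | None = None,
    signal_min: float = 0.0,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Threshold, radial-profile and extent-measure a labelled batch."""
    rule = rule or angular.default_purple_rule()
    t0 = time.perf_counter()
    df = angular.measure_batch(images, ellipses, rule, groups, signal_min=signal_min, ids=ids)
    log.info("angular-extent n=%d signal_min=%s (%.2fs)", len(images), signal_min, time.perf_counter() - t0)
    return df


def compare_groups(
    df: pd.DataFrame, value_col: str, group_col: str = "group"
) -> pd.DataFrame:
    """One-row summary of a two-group comparison of ``value_col``."""
    labels = list(pd.unique(df[group_col]))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {labels}")
    a = df.loc[df[group_col] == labels[0], value_col].to_numpy(dtype=float)
    b = df.loc[df[group_col] == labels[1], value_col].to_numpy(dtype=float)
    cmp = groupstats.two_sample_t(a, b)
    return pd.DataFrame(
        [
            {
                "group_a": labels[0],
                "group_b": labels[1],
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "mean_a": cmp.mean_a,
                "mean_b": cmp.mean_b,
                "sem_a": cmp.sem_a,
                "sem_b": cmp.sem_b,
                "t_stat": cmp.t_stat,
                "df": cmp.df,
                "p_value": cmp.p_value,
            }
        ]
    )


def plot_group_profiles(groups: dict[str, axisprofile.GroupProfile], path: str | Path) -> None:
    """Mean +/- SEM ratio vs normalized ventral->dorsal position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, gp in groups.items():
        ax.plot(gp.positions, gp.mean_ratio, label=f"{name} (n={gp.n})")
        ax.fill_between(
            gp.positions,
            gp.mean_ratio - gp.sem_ratio,
            gp.mean_ratio + gp.sem_ratio,
            alpha=0.3,
        )
    ax.set_xlabel("position on ventral (0) → dorsal (1) axis")
    ax.set_ylabel("signal / nuclear intensity ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# config-driven entry point


def run_workflow(config: dict, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Execute a configured workflow; returns the output files written.

    The config must carry ``workflow`` (simulate | gradient-profile |
    angular-extent | compare), ``seed`` and ``output_dir`` plus the
    workflow's own section.  Outputs are deterministic for a fixed
    config, and each table records the seed and config hash.
    """
    workflow = config["workflow"]
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_workflow workflow=%s seed=%d out=%s config_sha256=%s",
             workflow, seed, out, io_utils.config_hash(config))

    if workflow == "simulate":
        return _run_simulate(config, out, seed)
    if workflow == "gradient-profile":
        return _run_gradient_profile(config, out, seed)
    if workflow == "angular-extent":
        return _run_angular_extent(config, out, seed)
    if workflow == "compare":
        return _run_compare(config, out, seed)
    raise ValueError(f"unknown workflow {workflow!r}")


def _run_simulate(config: dict, out: Path, seed: int) -> dict[str, Path]:
    kind = config.get("kind", "insitu")
    n = int(config.get("n", 1))
    written: dict[str, Path] = {}
    manifest = []
    if kind == "insitu":
        extents = config.get("extents")
        if extents is None:
            rng = np.random.default_rng(seed)
            extents = rng.uniform(0.1, 0.9, size=n)
        ims = simulate_insitu_batch(
            np.asarray(extents, dtype=float),
            noise_sigma=float(config.get("noise_sigma", 0.0)),
            seed=seed,
        )
        for i, (img, truth) in enumerate(ims):
            img_path = out / f"insitu_{i:03d}.png"
            gt_path = out / f"insitu_{i:03d}.truth.json"
            io_utils.write_rgb_image(img_path, img)
            io_utils.write_ground_truth(gt_path, {"true_extent_fraction": truth, "seed": seed})
            manifest.append({"id": f"insitu_{i:03d}", "file": img_path.name, "true_extent_fraction": truth})
            written[f"image_{i}"] = img_path
    elif kind == "gradient":
        slope = float(config.get("ratio_slope", 2.0))
        intercept = float(config.get("ratio_intercept", 1.0))
        ims = simulate_gradient_batch(
            n,
            lambda x: intercept + slope * x,
            noise_sigma=float(config.get("noise_sigma", 0.0)),
            nuclear_level=float(config.get("nuclear_level", 100.0)),
            seed=seed,
        )
        for i, (img, _truth) in enumerate(ims):
            img_path = out / f"gradient_{i:03d}.tif"
            io_utils.write_gradient_tiff(img_path, img)
            io_utils.write_ground_truth(
                out / f"gradient_{i:03d}.truth.json",
                {"ratio_intercept": intercept, "ratio_slope": slope, "seed": seed},
            )
            manifest.append({"id": f"gradient_{i:03d}", "file": img_path.name})
            written[f"image_{i}"] = img_path
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    manifest_path = out / "manifest.csv"
    io_utils.write_table(pd.DataFrame(manifest), manifest_path, seed=seed, config=config)
    written["manifest"] = manifest_path
    return written


def _parse_roi(section: dict) -> axisprofile.RectROI:
    return axisprofile.RectROI(
        top=int(section.get("top", 0)),
        left=int(section.get("left", 0)),
        height=int(section.get("height", axisprofile.DEFAULT_ROI_HEIGHT)),
        width=int(section.get("width", axisprofile.DEFAULT_ROI_WIDTH)),
        axis=section.get("axis", "width"),
    )


def _run_gradient_profile(config: dict, out: Path, seed: int) -> dict[str, Path]:
    roi = _parse_roi(config.get("roi", {}))
    images_by_group: dict[str, list[np.ndarray]] = {}
    flags_by_group: dict[str, list[bool]] = {}
    for item in config["inputs"]:
        img = io_utils.read_image(item["path"]) if "path" in item else io_utils.assemble_channels(
            item["signal"], item["nuclear"]
        )
        grp = item.get("group", "all")
        images_by_group.setdefault(grp, []).append(np.asarray(img, dtype=float))
        flags_by_group.setdefault(grp, []).append(bool(item.get("ventral_first", True)))
    profiles, groups = gradient_profile_groups(
        images_by_group,
        roi,
        target_bins=int(config.get("target_bins", 100)),
        ventral_first=flags_by_group,
        nuclear_floor=config.get("nuclear_floor"),
    )
    written: dict[str, Path] = {}
    for grp, plist in profiles.items():
        rows = []
        for i, p in enumerate(plist):
            for pos, sig, nuc, rat, val in zip(p.positions, p.signal, p.nuclear, p.ratio, p.valid_mask):
                rows.append({"embryo": i, "position": pos, "signal": sig, "nuclear": nuc,
                             "ratio": rat, "valid": bool(val)})
        path = out / f"profiles_{grp}.csv"
        io_utils.write_table(pd.DataFrame(rows), path, seed=seed, config=config)
        written[f"profiles_{grp}"] = path
        gp = groups[grp]
        gpath = out / f"group_{grp}.csv"
        io_utils.write_table(
            pd.DataFrame({"position": gp.positions, "mean_ratio": gp.mean_ratio,
                          "sem_ratio": gp.sem_ratio, "n": gp.n}),
            gpath, seed=seed, config=config,
        )
        written[f"group_{grp}"] = gpath
    if config.get("plot", False):
        plot_path = out / "group_profiles.png"
        plot_group_profiles(groups, plot_path)
        written["plot"] = plot_path
    return written


def _run_angular_extent(config: dict, out: Path, seed: int) -> dict[str, Path]:
    rule = rule_from_config(config.get("threshold"))
    images, ellipses, groups, ids = [], [], [], []
    for item in config["inputs"]:
        images.append(io_utils.read_image(item["path"]))
        row, col, a, b, *rot = item["ellipse"]
        ellipses.append(angular.EllipseROI((float(row), float(col)), float(a), float(b),
                                           float(rot[0]) if rot else 0.0))
        groups.append(item.get("group", "all"))
        ids.append(item.get("id", Path(item["path"]).stem))
    df = extent_table(images, ellipses, groups, rule=rule,
                      signal_min=float(config.get("signal_min", 0.0)), ids=ids)
    written: dict[str, Path] = {}
    if config.get("write_visualizations", False):
        for img, img_id in zip(images, ids):
            _, vis = angular.threshold_stain(img, rule)
            vp = out / f"{img_id}_stain.png"
            io_utils.write_rgb_image(vp, vis)
            written[f"vis_{img_id}"] = vp
    path = out / "extent.csv"
    io_utils.write_table(df, path, seed=seed, config=config)
    written["extent"] = path
    return written


def _run_compare(config: dict, out: Path, seed: int) -> dict[str, Path]:
    df = io_utils.read_table(config["input"])
    result = compare_groups(df, config.get("value_col", "extent_fraction"),
                            config.get("group_col", "group"))
    path = out / "comparison.csv"
    io_utils.write_table(result, path, seed=seed, config=config)
    return {"comparison": path}
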