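"""End-to-end orchestration over a directory of photographs.

For every image: blue-band threshold, binarization, sub-image gap analysis
and cover fractions.  Images are grouped into trees by a filename pattern
(default ``<tree_id>_<quadrant>.<ext>``, the four-quadrant photo protocol);
per tree, pixel counts are pooled (or per-image LAI values averaged), the
extinction coefficient is supplied by the configured scheme, and Beer's-law
LAI is computed.  With a ground-truth table the measured extinction
coefficient and the validation statistics are produced as well.

Outputs are CSV files with fixed 6-significant-digit floats and stable row
order, so re-running on identical inputs is byte-identical.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import canopy_metrics, extinction_models, gap_analysis, imaging
from .evaluation import eval_stats, regression_check
from .extinction_models import FF_MODEL_PRESETS, FfModel
from .light_interception import read_ceptometer_csv

__all__ = ["RunConfig", "RunSummary", "validate_config", "load_config", "run_pipeline"]

logger = logging.getLogger("canopylai")

DEFAULT_GROUPING = r"(?P<tree>.+)_(?P<quadrant>\d+)\.(?:png|jpe?g|PNG|JPE?G)$"

_KNOWN_KEYS = {
    "image_dir", "grouping_pattern", "subdivision", "big_gap_ratio",
    "k_scheme", "k", "k_model", "ic_slope", "smooth_window",
    "ceptometer_csv", "ground_truth_csv", "aggregation", "output_dir", "seed",
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    image_dir: Path
    output_dir: Path = Path("canopylai_out")
    grouping_pattern: str = DEFAULT_GROUPING
    subdivision: int = gap_analysis.DEFAULT_SUBDIVISION
    big_gap_ratio: float = gap_analysis.DEFAULT_BIG_GAP_RATIO
    smooth_window: int = imaging.DEFAULT_SMOOTH_WINDOW
    k_scheme: str = "constant_k"
    k: float = extinction_models.DEFAULT_CONSTANT_K
    k_model: str | FfModel = "whole_dataset_exp"
    ic_slope: float = extinction_models.DEFAULT_IC_SLOPE
    ceptometer_csv: Path | None = None
    ground_truth_csv: Path | None = None
    aggregation: str = "pooled"
    seed: int | None = None


@dataclass(frozen=True)
class RunSummary:
    n_images: int
    n_trees: int
    outputs: tuple[Path, ...]
    warnings: tuple[str, ...] = field(default_factory=tuple)


def load_config(path: str | Path) -> RunConfig:
    """Parse a ``key = value`` text file into a validated RunConfig."""
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _KNOWN_KEYS:
            raise ValueError(f"{path}, line {lineno}: unknown key {key!r}")
        kv[key] = value

    if "image_dir" not in kv:
        raise ValueError("config must set image_dir")
    cfg = RunConfig(image_dir=Path(kv.pop("image_dir")))
    casts = {
        "subdivision": int, "smooth_window": int, "seed": int,
        "big_gap_ratio": float, "k": float, "ic_slope": float,
        "output_dir": Path, "ceptometer_csv": Path, "ground_truth_csv": Path,
    }
    for key, value in kv.items():
        cfg = replace(cfg, **{key: casts.get(key, str)(value)})
    return validate_config(cfg)


def validate_config(config: RunConfig) -> RunConfig:
    """Check consistency and normalise paths; raises naming the bad field."""
    if config.subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    if config.big_gap_ratio <= 0:
        raise ValueError("big_gap_ratio must be positive")
    if config.smooth_window < 1 or config.smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if config.k_scheme not in ("constant_k", "k_from_ff", "k_from_ic"):
        raise ValueError(f"unknown k_scheme {config.k_scheme!r}")
    if config.k_scheme == "k_from_ic" and config.ceptometer_csv is None:
        raise ValueError("k_scheme = k_from_ic requires ceptometer_csv")
    if config.k_scheme == "constant_k" and config.k <= 0:
        raise ValueError("constant k must be positive")
    if isinstance(config.k_model, str) and config.k_model not in FF_MODEL_PRESETS:
        raise ValueError(
            f"unknown k_model preset {config.k_model!r}; "
            f"available: {sorted(FF_MODEL_PRESETS)}"
        )
    if config.aggregation not in ("pooled", "per_image_mean"):
        raise ValueError(f"unknown aggregation {config.aggregation!r}")
    return replace(
        config,
        image_dir=Path(config.image_dir),
        output_dir=Path(config.output_dir),
    )


def _fmt(x: float) -> str:
    """Fixed-notation float with 6 significant digits (byte-stable reruns)."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if x != x:  # NaN
        return ""
    return np.format_float_positional(
        float(x), precision=6, unique=False, fractional=False
    ).rstrip(".")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(_fmt)
    df.to_csv(path, index=False)


def _tree_k(config: RunConfig, f_f: float, i_c_by_tree, tree_id: str):
    if config.k_scheme == "constant_k":
        return extinction_models.constant_k(config.k)
    if config.k_scheme == "k_from_ff":
        return extinction_models.k_from_ff(f_f, config.k_model)
    if tree_id not in i_c_by_tree:
        raise ValueError(
            f"k_scheme = k_from_ic but no ceptometer row for tree {tree_id!r}"
        )
    return extinction_models.k_from_ic(i_c_by_tree[tree_id].i_c, config.ic_slope)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Process a directory of upward-looking photographs into per-image,
    per-tree and (optionally) evaluation CSV reports."""
    config = validate_config(config)
    warnings_log: list[str] = []

    pattern = re.compile(config.grouping_pattern)
    files = sorted(p for p in Path(config.image_dir).iterdir() if p.is_file())
    grouped: dict[str, list[tuple[int, Path]]] = {}
    n_matched = 0
    for f in files:
        m = pattern.search(f.name)
        if m is None:
            warnings_log.append(f"unmatched file skipped: {f.name}")
            continue
        n_matched += 1
        grouped.setdefault(m.group("tree"), []).append((int(m.group("quadrant")), f))
    if n_matched == 0:
        raise ValueError(
            f"no images in {config.image_dir} match pattern {config.grouping_pattern!r}"
        )
    for w in warnings_log:
        logger.warning(w)

    i_c_by_tree = (
        read_ceptometer_csv(config.ceptometer_csv) if config.ceptometer_csv else {}
    )

    per_image_rows = []
    per_tree_rows = []
    for tree_id in sorted(grouped):
        quadrants = sorted(grouped[tree_id])
        if len(quadrants) != 4:
            msg = f"tree {tree_id}: {len(quadrants)} image(s) instead of 4; processing anyway"
            warnings_log.append(msg)
            logger.warning(msg)

        counts_list = []
        image_lais = []
        for quadrant, path in quadrants:
            image = imaging.load_image(path, source_id=f"{tree_id}_{quadrant}")
            band = imaging.extract_blue(image)
            hist = imaging.blue_histogram(band)
            threshold = imaging.find_threshold(hist, config.smooth_window)
            mask = imaging.binarize(band, threshold)
            counts = gap_analysis.analyze_gaps(
                mask, config.subdivision, config.big_gap_ratio
            )
            cover = gap_analysis.cover_fractions(counts)
            logger.info("%s: threshold=%d f_f=%.4f", image.source_id, threshold, cover.f_f)
            counts_list.append(counts)
            per_image_rows.append(
                {
                    "tree_id": tree_id,
                    "quadrant": quadrant,
                    "source_id": image.source_id,
                    "threshold_used": threshold,
                    "g_T": counts.g_T,
                    "g_L": counts.g_L,
                    "T_P": counts.T_P,
                    "f_f": cover.f_f,
                    "f_c": cover.f_c,
                }
            )
            if config.aggregation == "per_image_mean":
                image_lais.append(_image_lai(config, cover, i_c_by_tree, tree_id))

        pooled = gap_analysis.pool_counts(counts_list)
        cover = gap_analysis.cover_fractions(pooled)
        f_f, f_c = cover.f_f, cover.f_c
        if f_f == 0.0 or f_c == 0.0:
            phi, omega0, lai, k_used, tag = float("nan"), float("nan"), 0.0, float("nan"), config.k_scheme
        else:
            phi = canopy_metrics.crown_porosity(f_f, f_c)
            omega0 = canopy_metrics.clumping_index(f_f, phi) if phi > 0 else 0.0
            est = _tree_k(config, f_f, i_c_by_tree, tree_id)
            k_used, tag = est.k, est.scheme
            if config.aggregation == "per_image_mean":
                lai = float(np.mean(image_lais))
            else:
                lai = canopy_metrics.lai_from_cover(f_c, phi, omega0, k_used, tag).lai
            logger.info("%s: scheme=%s k=%.4f LAI=%.4f", tree_id, tag, k_used, lai)
        per_tree_rows.append(
            {
                "tree_id": tree_id,
                "n_images": len(quadrants),
                "f_f": f_f,
                "f_c": f_c,
                "phi": phi,
                "omega0": omega0,
                "k_used": k_used,
                "method_tag": tag,
                "lai": lai,
            }
        )

    config.output_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    per_image_df = pd.DataFrame(per_image_rows).sort_values(["tree_id", "quadrant"])
    per_tree_df = pd.DataFrame(per_tree_rows).sort_values("tree_id")

    if config.ground_truth_csv is not None:
        gt = pd.read_csv(config.ground_truth_csv)
        if "tree_id" not in gt.columns or "lai_d" not in gt.columns:
            raise ValueError("ground-truth CSV must have tree_id and lai_d columns")
        gt["tree_id"] = gt["tree_id"].astype(str)
        per_tree_df = per_tree_df.merge(gt[["tree_id", "lai_d"]], on="tree_id", how="left")
        k_m = []
        for _, row in per_tree_df.iterrows():
            if row.notna()["lai_d"] and 0 < row["phi"] < 1:
                k_m.append(
                    canopy_metrics.invert_k(
                        row["f_c"], row["phi"], row["omega0"], row["lai_d"]
                    ).k_M
                )
            else:
                k_m.append(float("nan"))
        per_tree_df["k_M"] = k_m

        paired = per_tree_df.dropna(subset=["lai_d"])
        if len(paired) >= 2:
            stats = eval_stats(paired["lai_d"].to_numpy(), paired["lai"].to_numpy())
            eval_row = {
                "method_tag": per_tree_df["method_tag"].iloc[0],
                "n": stats.n,
                "rmse": stats.rmse, "rmse_pct": stats.rmse_pct,
                "mae": stats.mae, "mae_pct": stats.mae_pct,
                "mbe": stats.mbe, "mbe_pct": stats.mbe_pct,
                "d": stats.d, "r2": stats.r2,
            }
            if len(paired) >= 3 and np.ptp(paired["lai_d"].to_numpy()) > 0:
                check = regression_check(
                    paired["lai_d"].to_numpy(), paired["lai"].to_numpy()
                )
                eval_row.update(
                    slope=check.slope,
                    intercept=check.intercept,
                    p_intercept_eq_0=check.p_intercept_eq_0,
                    p_slope_eq_1=check.p_slope_eq_1,
                )
            eval_path = config.output_dir / "evaluation.csv"
            _write_csv(pd.DataFrame([eval_row]), eval_path)
            outputs.append(eval_path)

    per_image_path = config.output_dir / "per_image.csv"
    per_tree_path = config.output_dir / "per_tree.csv"
    _write_csv(per_image_df, per_image_path)
    _write_csv(per_tree_df, per_tree_path)
    outputs = [per_image_path, per_tree_path] + outputs

    return RunSummary(
        n_images=n_matched,
        n_trees=len(grouped),
        outputs=tuple(outputs),
        warnings=tuple(warnings_log),
    )


def _image_lai(config: RunConfig, cover, i_c_by_tree, tree_id: str) -> float:
    """Per-image LAI for the per_image_mean aggregation mode."""
    if cover.f_f == 0.0 or cover.f_c == 0.0:
        return 0.0
    phi = canopy_metrics.crown_porosity(cover.f_f, cover.f_c)
    omega0 = canopy_metrics.clumping_index(cover.f_f, phi) if phi > 0 else 0.0
    est = _tree_k(config, cover.f_f, i_c_by_tree, tree_id)
    return canopy_metrics.lai_from_cover(cover.f_c, phi, omega0, est.k, est.scheme).lai
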