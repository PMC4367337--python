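"""Synthetic canopy scenes and Beer's-law-consistent datasets.

Everything here exists so the full pipeline can be exercised without field
photographs: rendered upward-looking scenes whose pixel-level foliage, sky
and crown fractions are known exactly, and per-tree tabular records whose
(f_f, f_c, Φ, Ω(0), k, LAI, I_c) tuples satisfy the Beer's-law LAI equation
by construction.

Scenes are deliberately schematic: elliptical crown blobs filled with
foliage-toned pixels on a sky-toned background, with a seeded, exact-count
subset of within-crown pixels flipped to sky to realise a target crown
porosity.  Foliage and sky blue-band tone ranges never overlap, so the tone
classes remain perfectly separable — ground truth is exact rather than in
expectation.  Gaussian tone noise is truncated to each class range.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .canopy_metrics import clumping_index, crown_porosity, lai_from_cover
from .extinction_models import DEFAULT_IC_SLOPE, FfModel
from .imaging import CanopyImage

__all__ = [
    "Crown",
    "SceneSpec",
    "SceneTruth",
    "BeerLawRecord",
    "render_scene",
    "simulate_beer_law_dataset",
    "make_orchard",
    "write_orchard",
]

# default blue-band tone ranges: foliage is the dark class, sky the bright one
DEFAULT_FOLIAGE_BLUE = (10, 60)
DEFAULT_SKY_BLUE = (150, 220)


@dataclass(frozen=True)
class Crown:
    """One elliptical crown blob: center (row, col) in pixels, semi-axes
    (row, col) in pixels, orientation in radians (counter-clockwise)."""

    center: tuple[float, float]
    radii: tuple[float, float]
    orientation: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one rendered canopy scene."""

    width_px: int = 512
    height_px: int = 384
    crowns: tuple[Crown, ...] = ()
    within_crown_porosity: float = 0.15
    foliage_blue_range: tuple[int, int] = DEFAULT_FOLIAGE_BLUE
    sky_blue_range: tuple[int, int] = DEFAULT_SKY_BLUE
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("scene dimensions must be positive")
        if not 0.0 <= self.within_crown_porosity <= 1.0:
            raise ValueError("within_crown_porosity must lie in [0, 1]")
        f_lo, f_hi = self.foliage_blue_range
        s_lo, s_hi = self.sky_blue_range
        if not (0 <= f_lo <= f_hi <= 255 and 0 <= s_lo <= s_hi <= 255):
            raise ValueError("tone ranges must lie within [0, 255]")
        if f_hi >= s_lo:
            raise ValueError(
                "foliage tone range must lie entirely below the sky tone range "
                f"(got foliage ≤ {f_hi}, sky ≥ {s_lo})"
            )
        object.__setattr__(self, "crowns", tuple(self.crowns))


@dataclass(frozen=True)
class SceneTruth:
    """Exact pixel-level ground truth of a rendered scene."""

    true_foliage_fraction: float
    true_crown_fraction: float
    foliage_mask: np.ndarray  # bool, True = foliage


@dataclass(frozen=True)
class BeerLawRecord:
    """One simulated tree whose fields satisfy the LAI equation exactly."""

    tree_id: str
    f_f: float
    f_c: float
    phi: float
    omega0: float
    k_true: float
    lai_true: float
    i_c: float


def _crown_mask(spec: SceneSpec) -> np.ndarray:
    rows, cols = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    for crown in spec.crowns:
        cr, cc = crown.center
        ry, rx = crown.radii
        th = crown.orientation
        dr = rows - cr
        dc = cols - cc
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        mask |= (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    return mask


def _tone_field(
    rng: np.random.Generator, shape: tuple[int, int], lo: int, hi: int, sd: float
) -> np.ndarray:
    """Class tones: range midpoint plus truncated Gaussian noise, clipped so
    values never leave [lo, hi] (class ranges therefore never overlap)."""
    center = (lo + hi) / 2.0
    if sd == 0:
        return np.full(shape, int(round(center)), dtype=np.uint8)
    tones = rng.normal(center, sd, size=shape)
    return np.clip(np.rint(tones), lo, hi).astype(np.uint8)


def render_scene(spec: SceneSpec) -> tuple[CanopyImage, SceneTruth]:
    """Rasterize a scene and report its exact ground truth.

    The ellipse interiors form the crown region; an exact count
    ``round(porosity × crown pixels)`` of seeded-random interior pixels is
    flipped to sky tone, so the reported fractions are exact pixel tallies,
    not expectations.
    """
    rng = np.random.default_rng(spec.seed)
    crown = _crown_mask(spec)
    n_crown = int(crown.sum())

    foliage = crown.copy()
    n_flip = int(round(spec.within_crown_porosity * n_crown))
    if n_flip > 0:
        interior = np.flatnonzero(crown.ravel())
        flip = rng.choice(interior, size=n_flip, replace=False)
        foliage.ravel()[flip] = False

    h, w = spec.height_px, spec.width_px
    blue = _tone_field(rng, (h, w), *spec.sky_blue_range, spec.noise_sd)
    fol_tones = _tone_field(rng, (h, w), *spec.foliage_blue_range, spec.noise_sd)
    blue[foliage] = fol_tones[foliage]

    # red/green channels only carry plausible colour; analysis ignores them
    red = np.where(foliage, 45, 180).astype(np.uint8)
    green = np.where(foliage, 95, 200).astype(np.uint8)
    pixels = np.stack([red, green, blue], axis=-1)

    # expressed as 1 - gaps/total, matching the cover-fraction definition
    # bit-for-bit so exact pipeline-recovery comparisons are meaningful
    n_px = foliage.size
    truth = SceneTruth(
        true_foliage_fraction=1.0 - float(n_px - int(foliage.sum())) / n_px,
        true_crown_fraction=1.0 - float(n_px - n_crown) / n_px,
        foliage_mask=foliage,
    )
    return CanopyImage(pixels), truth


def simulate_beer_law_dataset(
    n_trees: int,
    k_model: FfModel | float = FfModel("exponential", 0.136, 1.99),
    noise_sd: float = 0.0,
    ic_slope: float = DEFAULT_IC_SLOPE,
    seed: int = 0,
    ff_range: tuple[float, float] = (0.6, 0.9),
    fc_range: tuple[float, float] = (0.75, 1.0),
    ic_jitter_sd: float = 0.0,
) -> list[BeerLawRecord]:
    """Draw per-tree records consistent with the Beer's-law LAI equation.

    Cover fractions are drawn uniformly from ranges spanning what mature
    apple orchards show (f_f ∈ [0.6, 0.9], f_c ∈ [0.75, 1.0], f_f ≤ f_c);
    porosity and clumping follow from them; k comes from ``k_model``
    (a fitted k(f_f) model or a constant) with multiplicative lognormal
    noise of scale ``noise_sd``; LAI is then the exact Beer's-law value and
    I_c = k/ic_slope.  Noise draws that would push I_c above 1 are redrawn
    (truncation), keeping records in the valid domain of the interception
    proxy.  ``ic_jitter_sd`` optionally adds lognormal jitter to I_c to
    break the exact proxy tie.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    lo_f, hi_f = ff_range
    lo_c, hi_c = fc_range
    if not (0 < lo_f <= hi_f < 1 and 0 < lo_c <= hi_c <= 1):
        raise ValueError("invalid cover-fraction ranges")
    if hi_f > hi_c:
        raise ValueError("ff_range must not exceed fc_range at the top")

    rng = np.random.default_rng(seed)
    records: list[BeerLawRecord] = []
    for i in range(n_trees):
        f_c = float(rng.uniform(lo_c, hi_c))
        f_f = float(rng.uniform(lo_f, min(hi_f, f_c)))
        phi = crown_porosity(f_f, f_c)
        omega0 = clumping_index(f_f, phi)
        k_base = k_model.predict(f_f) if isinstance(k_model, FfModel) else float(k_model)
        for _ in range(1000):
            k_true = k_base * float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else k_base
            if k_true / ic_slope <= 1.0:
                break
        else:
            raise ValueError(
                f"cannot draw k <= ic_slope for f_f={f_f:.3f}; "
                "k_model and ic_slope are incompatible"
            )
        lai = lai_from_cover(f_c, phi, omega0, k_true).lai
        i_c = k_true / ic_slope
        if ic_jitter_sd > 0:
            i_c = min(i_c * float(np.exp(rng.normal(0.0, ic_jitter_sd))), 1.0)
        records.append(
            BeerLawRecord(
                tree_id=f"T{i + 1:02d}",
                f_f=f_f, f_c=f_c, phi=phi, omega0=omega0,
                k_true=k_true, lai_true=lai, i_c=i_c,
            )
        )
    return records


def make_orchard(
    n_trees: int = 10,
    quadrants: int = 4,
    seed: int = 0,
    width_px: int = 512,
    height_px: int = 384,
    noise_sd: float = 0.0,
) -> list[tuple[str, int, CanopyImage, SceneTruth]]:
    """Render a demo orchard: ``quadrants`` scenes per tree with
    tree-specific crown geometry and porosity.

    Returns (tree_id, quadrant, image, truth) tuples, ordered by tree then
    quadrant.  Per-tree appearance (crown count, size, porosity) varies with
    the seed; the four quadrant views of one tree share its porosity but
    draw separate crown layouts, mimicking the four-quadrant photo protocol.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, int, CanopyImage, SceneTruth]] = []
    for t in range(n_trees):
        tree_id = f"T{t + 1:02d}"
        porosity = float(rng.uniform(0.05, 0.25))
        n_crowns = int(rng.integers(1, 4))
        for q in range(1, quadrants + 1):
            crowns = []
            for _ in range(n_crowns):
                cy = float(rng.uniform(0.3, 0.7) * height_px)
                cx = float(rng.uniform(0.3, 0.7) * width_px)
                ry = float(rng.uniform(0.25, 0.45) * height_px)
                rx = float(rng.uniform(0.25, 0.45) * width_px)
                theta = float(rng.uniform(0, math.pi))
                crowns.append(Crown((cy, cx), (ry, rx), theta))
            spec = SceneSpec(
                width_px=width_px,
                height_px=height_px,
                crowns=tuple(crowns),
                within_crown_porosity=porosity,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, truth = render_scene(spec)
            out.append((tree_id, q, img, truth))
    return out


def write_orchard(
    output_dir: str | Path,
    n_trees: int = 10,
    quadrants: int = 4,
    seed: int = 0,
    ic_slope: float = DEFAULT_IC_SLOPE,
    k_model: FfModel | float = FfModel("exponential", 0.136, 1.99),
    **orchard_kwargs,
) -> Path:
    """Materialise a demo orchard on disk.

    Writes ``images/<tree>_<quadrant>.png``, a ``truth.csv`` with exact
    per-image fractions, a ``ceptometer.csv`` (one incident and five
    identical below-canopy PAR readings per tree, consistent with each
    tree's Beer's-law I_c), and a ``ground_truth.csv`` whose lai_d is the
    Beer's-law LAI of the tree's true pooled cover fractions.
    """
    output_dir = Path(output_dir)
    img_dir = output_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    scenes = make_orchard(n_trees=n_trees, quadrants=quadrants, seed=seed, **orchard_kwargs)
    truth_rows = []
    per_tree: dict[str, list[SceneTruth]] = {}
    for tree_id, q, img, truth in scenes:
        Image.fromarray(img.pixels, mode="RGB").save(img_dir / f"{tree_id}_{q}.png")
        truth_rows.append(
            {
                "tree_id": tree_id,
                "quadrant": q,
                "true_foliage_fraction": truth.true_foliage_fraction,
                "true_crown_fraction": truth.true_crown_fraction,
            }
        )
        per_tree.setdefault(tree_id, []).append(truth)
    pd.DataFrame(truth_rows).to_csv(output_dir / "truth.csv", index=False)

    cep_rows = []
    gt_rows = []
    i_o = 2000.0  # µmol m⁻² s⁻¹, a clear-sky incident PAR magnitude
    for tree_id, truths in per_tree.items():
        f_f = float(np.mean([t.true_foliage_fraction for t in truths]))
        f_c = float(np.mean([t.true_crown_fraction for t in truths]))
        phi = crown_porosity(f_f, f_c)
        omega0 = clumping_index(f_f, phi)
        k = k_model.predict(f_f) if isinstance(k_model, FfModel) else float(k_model)
        lai = lai_from_cover(f_c, phi, omega0, k).lai
        i_c = min(k / ic_slope, 1.0)
        below = i_o * (1.0 - i_c)
        cep_rows.append(
            {"tree_id": tree_id, "i_o": i_o, **{f"below_{j}": below for j in range(1, 6)}}
        )
        gt_rows.append({"tree_id": tree_id, "lai_d": lai})
    pd.DataFrame(cep_rows).to_csv(output_dir / "ceptometer.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(output_dir / "ground_truth.csv", index=False)
    return output_dir
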