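"""Synthetic clone cohorts for the potency-prediction pipeline.

No public image set exists for single-cell-derived mesenchymal stem cell
(MSC) clones imaged through a serial-passage study, so this module
generates cohorts whose *statistical* structure matches what the analysis
assumes:

* ~15 clones with serial-passage potencies spanning 7-13 passages,
  assigned round-robin over the range (guaranteeing coverage) and then
  shuffled;
* per-well cell populations growing from hundreds to tens of thousands of
  cells over the 6-90 h time course, distributed over 64 fields of view;
* population statistics of a handful of descriptor-statistics coupled
  affinely to potency: higher-potency clones carry a larger spread of the
  GLCM texture descriptors at early times (more proliferating, texturally
  active cells) and a smaller spread of Length and Compactness (less
  uncontrolled elongation), and a lower mean texture Correlation;
* a proliferating subpopulation of small, bright, round cells whose
  prevalence increases with potency;
* a clone growth rate only weakly coupled to potency (population
  R^2 = 0.09 by default), so growth alone cannot predict potency.

Two tiers are generated. The fast *tabular* tier samples per-cell
descriptor rows directly from the per-clone distributions and is what the
profiling/modeling stages consume. The *image* tier rasterizes a chosen
(clone, time, FOV) into a phase-contrast-like frame plus a ground-truth
label mask and exists to exercise segmentation and descriptor
measurement. The renderer is deliberately simple (textured ellipses and
bright disks on a vignetted background), not an optics simulation.

For every coupled descriptor the drawn per-cell column is affinely
rescaled per clone x time point so that the pooled sample mean and SD
*exactly* equal the affine-in-potency targets (plus clone-level noise
scaled by ``noise_sd``). In the noiseless limit the coupled population
statistics are therefore exact affine functions of potency, which gives
the downstream model-recovery tests a sharp ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES
from .profiling import TIME_POINTS_H
from .segmentation import DEFAULT_PIXEL_SIZE_UM, ImageFrame, LabelMask

CouplingKey = tuple[str, str, int]  # (descriptor, "mean"|"SD", time_h)

#: default affine coupling coefficients (units of the descriptor per
#: passage of potency), applied at the early time points 6-18 h; signs
#: follow the direction of the reported model structure (texture SDs and
#: shape SDs move oppositely with potency).
DEFAULT_COUPLING: dict[CouplingKey, float] = {}
for _t in (6, 12, 18):
    DEFAULT_COUPLING[("Correlation", "SD", _t)] = +0.007
    DEFAULT_COUPLING[("Energy", "SD", _t)] = +0.006
    DEFAULT_COUPLING[("Length", "SD", _t)] = -0.7
    DEFAULT_COUPLING[("Compactness", "SD", _t)] = -0.012
    DEFAULT_COUPLING[("Correlation", "mean", _t)] = -0.015

#: potency-independent base values (at the reference potency 10) for the
#: statistically controlled descriptors; means may drift linearly in time
#: (cells spread as the culture matures).
_BASE: dict[str, dict[str, float]] = {
    "Length":      {"mean": 52.0, "SD": 8.0,  "mean_trend_per_h": 0.10},
    "Compactness": {"mean": 2.2,  "SD": 0.18, "mean_trend_per_h": 0.0},
    "Correlation": {"mean": 0.45, "SD": 0.06, "mean_trend_per_h": 0.0},
    "Energy":      {"mean": 0.30, "SD": 0.05, "mean_trend_per_h": 0.0},
}
#: raw-draw z offsets of the proliferating (round) class, in SD units
_ROUND_Z_OFFSET = {"Length": -1.5, "Compactness": -1.0,
                   "Correlation": +0.5, "Energy": +0.4}
_Z_TRUNC = 3.5            # truncation of the raw standard-normal draws
_MAX_FOLD_BOUND = 8.0     # growth-fold draws are clipped below this


class SpecValidationError(ValueError):
    """A SyntheticCohortSpec field failed validation; names the field."""


@dataclass
class SyntheticCohortSpec:
    """Study-condition parameters of a synthetic clone cohort."""

    n_clones: int = 15
    potency_range: tuple[int, int] = (7, 13)
    cells_per_well_range: tuple[int, int] = (300, 100_000)
    time_points: tuple[int, ...] = TIME_POINTS_H
    n_fovs: int = 64
    coupling: Mapping[CouplingKey, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING))
    noise_sd: float = 1.0
    growth_potency_r2_target: float = 0.09
    mean_growth_fold: float = 4.8
    growth_fold_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise SpecValidationError(f"n_clones must be >= 1, got {self.n_clones}")
        lo, hi = self.potency_range
        if not (3 <= lo <= hi):
            raise SpecValidationError(
                f"potency_range must satisfy 3 <= lo <= hi, got {self.potency_range}")
        clo, chi = self.cells_per_well_range
        if not (2 <= clo <= chi):
            raise SpecValidationError(
                f"cells_per_well_range must satisfy 2 <= lo <= hi, "
                f"got {self.cells_per_well_range}")
        if self.n_fovs < 1:
            raise SpecValidationError(f"n_fovs must be >= 1, got {self.n_fovs}")
        if not self.time_points:
            raise SpecValidationError("time_points is empty")
        for t in self.time_points:
            if t <= 0 or t % 6 != 0:
                raise SpecValidationError(
                    f"time_points must be positive multiples of 6 h, got {t}")
        # the stock coupling follows a shortened time grid automatically;
        # explicit couplings are validated strictly against it
        if dict(self.coupling) == DEFAULT_COUPLING:
            self.coupling = {k: v for k, v in DEFAULT_COUPLING.items()
                             if k[2] in self.time_points}
        for key, c in dict(self.coupling).items():
            d, s, t = key
            if d not in DESCRIPTOR_NAMES:
                raise SpecValidationError(f"coupling: unknown descriptor {d!r}")
            if s not in ("mean", "SD"):
                raise SpecValidationError(f"coupling: statistic must be mean|SD, got {s!r}")
            if t not in self.time_points:
                raise SpecValidationError(
                    f"coupling: time {t} h not in time_points")
            if not math.isfinite(c):
                raise SpecValidationError(f"coupling: non-finite coefficient for {key}")
        if self.noise_sd < 0:
            raise SpecValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.growth_potency_r2_target < 1.0:
            raise SpecValidationError(
                "growth_potency_r2_target must be in [0, 1), "
                f"got {self.growth_potency_r2_target}")

    def as_jsonable(self) -> dict:
        d = asdict(self)
        d["coupling"] = {f"{k[0]}_{k[1]} ({k[2]} h)": v
                         for k, v in dict(self.coupling).items()}
        return d


@dataclass
class SyntheticClone:
    """One generated clone: cell table, ground-truth counts, potency."""

    clone_id: str
    potency: int
    cells: pd.DataFrame          # columns: clone_id, time_h, fov, cell_id, ...
    counts: dict[float, int]     # ground-truth cell count per time point
    growth_rate: float           # realized fold-change over the time course
    render_seed: int             # base entropy for frame rendering

    def cells_at(self, time_h: float) -> pd.DataFrame:
        return self.cells.loc[self.cells["time_h"] == time_h]


@dataclass
class RenderSpec:
    """Rasterization parameters of the image tier."""

    image_size: tuple[int, int] = (1000, 1000)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    background_level: float = 100.0
    background_noise_sd: float = 1.5
    vignetting_amplitude: float = 6.0
    spread_intensity_offset: float = 8.0
    spread_texture_sd: float = 14.0
    round_brightness: float = 185.0
    round_texture_sd: float = 8.0
    min_separation_px: float = 3.0
    max_place_tries: int = 500

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise SpecValidationError(f"image_size must be >= 64x64, got {self.image_size}")
        if self.pixel_size <= 0:
            raise SpecValidationError("pixel_size must be positive")


def assign_potencies(n_clones: int, potency_range: tuple[int, int],
                     rng: np.random.Generator) -> np.ndarray:
    """Round-robin over the potency range, then shuffle.

    Guarantees every value in the range appears once before any repeats,
    so 15 clones over 7..13 cover the whole range.
    """
    lo, hi = potency_range
    base = np.arange(lo, hi + 1)
    reps = int(np.ceil(n_clones / base.size))
    potencies = np.tile(base, reps)[:n_clones].astype(int)
    rng.shuffle(potencies)
    return potencies


def _truncated_normal(rng: np.random.Generator, n: int,
                      trunc: float = _Z_TRUNC) -> np.ndarray:
    z = rng.standard_normal(n)
    # redraw the (rare) tail instead of clipping, keeping the shape smooth
    bad = np.abs(z) > trunc
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > trunc
    return z


def _standardize_to(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale x so its sample mean/SD (ddof=1) equal (mean, sd)."""
    if x.size < 2:
        return np.full_like(x, mean)
    s = x.std(ddof=1)
    if s == 0:
        return np.full_like(x, mean)
    return (x - x.mean()) / s * sd + mean


def _target_stats(desc: str, potency: int, time_h: int,
                  coupling: Mapping[CouplingKey, float], noise_sd: float,
                  rng: np.random.Generator) -> tuple[float, float]:
    base = _BASE[desc]
    out = {}
    for stat in ("mean", "SD"):
        b = base[stat]
        if stat == "mean":
            b = b + base.get("mean_trend_per_h", 0.0) * (time_h - 6)
        coef = coupling.get((desc, stat, time_h), 0.0)
        noise_ref = abs(coef) if coef != 0.0 else 0.05 * abs(base[stat])
        eps = rng.standard_normal() if noise_sd > 0 else 0.0
        out[stat] = b + coef * (potency - 10) + noise_sd * noise_ref * eps
    # an SD target must stay positive
    out["SD"] = max(out["SD"], 0.02 * abs(base["SD"]))
    return out["mean"], out["SD"]


def _controlled_descriptors(coupling: Mapping[CouplingKey, float]) -> list[str]:
    ctrl = {k[0] for k in dict(coupling)}
    ctrl |= set(_BASE)  # base four are always statistically controlled
    unknown = ctrl - set(_BASE)
    if unknown:
        raise SpecValidationError(
            f"coupling on descriptor(s) {sorted(unknown)} is not supported: "
            f"statistically controlled descriptors are {sorted(_BASE)}")
    return [d for d in ("Length", "Compactness", "Correlation", "Energy")
            if d in ctrl]


def _round_fraction(potency: int) -> float:
    """Prevalence of the proliferating (round, bright) subpopulation."""
    return float(np.clip(0.04 + 0.012 * (potency - 7), 0.0, 0.35))


def _make_cells(n: int, potency: int, time_h: int, clone_id: str,
                spec: SyntheticCohortSpec, rng: np.random.Generator,
                pixel_size: float) -> pd.DataFrame:
    is_round = rng.random(n) < _round_fraction(potency)

    def z(desc: str) -> np.ndarray:
        zz = _truncated_normal(rng, n)
        return zz + np.where(is_round, _ROUND_Z_OFFSET.get(desc, 0.0), 0.0)

    raw = {d: z(d) for d in ("Length", "Compactness", "Correlation", "Energy")}
    # per-(clone, time, descriptor, stat) targets; rng order is fixed
    cols: dict[str, np.ndarray] = {}
    for d in ("Length", "Compactness", "Correlation", "Energy"):
        m, s = _target_stats(d, potency, time_h, dict(spec.coupling),
                             spec.noise_sd, rng)
        cols[d] = _standardize_to(raw[d], m, s)

    cols["Length"] = np.maximum(cols["Length"], 2.0)
    cols["Compactness"] = np.maximum(cols["Compactness"], 1.01)
    cols["Correlation"] = np.clip(cols["Correlation"], -1.0, 1.0)
    cols["Energy"] = np.clip(cols["Energy"], 1e-4, 1.0)

    aspect = np.where(
        is_round,
        1.0 + np.abs(rng.normal(0.0, 0.05, n)),
        1.0 + np.abs(rng.normal(0.55, 0.45, n)))
    aspect = np.clip(aspect, 1.0, 4.0)
    cols["AspectRatio"] = aspect
    cols["Breadth"] = cols["Length"] / aspect

    shape_jitter = np.clip(rng.normal(1.0, 0.06, n), 0.7, 1.3)
    area_spread = np.pi / 4.0 * cols["Length"] * cols["Breadth"] * shape_jitter
    area_round = np.clip(rng.normal(45.0, 10.0, n), 15.0, 80.0)
    area_um2 = np.where(is_round, area_round, area_spread)
    area_px = np.maximum(np.rint(area_um2 / pixel_size**2), 4).astype(int)
    cols["Area"] = area_px * pixel_size**2

    cols["Perimeter"] = np.sqrt(cols["Compactness"] * 4.0 * np.pi * cols["Area"])
    cols["Roundness"] = 1.0 / cols["Compactness"]
    cols["Solidity"] = np.clip(1.0 - np.abs(rng.normal(0.0, 0.03, n)), 0.7, 1.0)
    cols["IntensityMean"] = np.where(
        is_round, rng.normal(185.0, 10.0, n), rng.normal(118.0, 12.0, n))
    cols["IntensitySD"] = 2.0 + np.abs(rng.normal(13.0, 3.0, n))

    df = pd.DataFrame({
        "clone_id": clone_id,
        "time_h": float(time_h),
        "fov": rng.integers(0, spec.n_fovs, n),
        "cell_id": np.arange(1, n + 1),
        "area_px": area_px,
        **{d: cols[d] for d in DESCRIPTOR_NAMES},
        "proliferating": is_round,
        "degenerate": False,
    })
    return df


def _growth_folds(potencies: np.ndarray, spec: SyntheticCohortSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Growth folds with potency coupling solved for the target R^2.

    fold = mu + a (potency - mean) + e with a sigma_pot = rho sigma_g and
    sd(e) = sqrt(1 - rho^2) sigma_g, so the population squared correlation
    between fold and potency is exactly the target.
    """
    rho = math.sqrt(spec.growth_potency_r2_target)
    sigma_g = spec.growth_fold_sd
    pot = potencies.astype(float)
    sigma_pot = pot.std(ddof=1) if pot.size > 1 and pot.std(ddof=1) > 0 else 1.0
    a = rho * sigma_g / sigma_pot
    e = rng.normal(0.0, math.sqrt(max(1.0 - rho**2, 0.0)) * sigma_g, pot.size)
    folds = spec.mean_growth_fold + a * (pot - pot.mean()) + e
    return np.clip(folds, 1.05, _MAX_FOLD_BOUND)


def generate_cohort(spec: SyntheticCohortSpec) -> list[SyntheticClone]:
    """Generate the full tabular-tier cohort for a cohort spec.

    Deterministic: the same spec (including seed) yields a bit-identical
    cohort.
    """
    rng = np.random.default_rng(spec.seed)
    potencies = assign_potencies(spec.n_clones, spec.potency_range, rng)
    folds = _growth_folds(potencies, spec, rng)

    clo, chi = spec.cells_per_well_range
    n0_hi = max(clo, int(chi / _MAX_FOLD_BOUND))
    n0 = np.exp(rng.uniform(np.log(clo), np.log(max(n0_hi, clo + 1)),
                            spec.n_clones))

    t0, t1 = spec.time_points[0], spec.time_points[-1]
    span = max(t1 - t0, 1)
    clones: list[SyntheticClone] = []
    for i in range(spec.n_clones):
        clone_id = f"clone{i + 1:02d}"
        clone_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, i)))
        counts: dict[float, int] = {}
        tables = []
        for t in spec.time_points:
            frac = (t - t0) / span
            n_t = int(np.clip(round(n0[i] * folds[i] ** frac), clo, chi))
            counts[float(t)] = n_t
            tables.append(_make_cells(n_t, int(potencies[i]), int(t),
                                      clone_id, spec, clone_rng,
                                      DEFAULT_PIXEL_SIZE_UM))
        cells = pd.concat(tables, ignore_index=True)
        realized = counts[float(t1)] / counts[float(t0)]
        clones.append(SyntheticClone(
            clone_id=clone_id, potency=int(potencies[i]), cells=cells,
            counts=counts, growth_rate=float(realized),
            render_seed=int(spec.seed) & 0x7FFFFFFF))
    return clones


def cohort_cells(clones: Sequence[SyntheticClone]) -> pd.DataFrame:
    """Concatenated cell table of a cohort."""
    return pd.concat([c.cells for c in clones], ignore_index=True)


def cohort_labels(clones: Sequence[SyntheticClone]) -> pd.DataFrame:
    """Labels table: clone_id, potency, growth_rate."""
    return pd.DataFrame({
        "clone_id": [c.clone_id for c in clones],
        "potency": [c.potency for c in clones],
        "growth_rate": [c.growth_rate for c in clones],
    })


# ---------------------------------------------------------------------------
# image tier
# ---------------------------------------------------------------------------

class DensityError(RuntimeError):
    """More cells than can be placed without overlap at the frame size."""


def _place_cells(table: pd.DataFrame, shape: tuple[int, int],
                 pixel_size: float, min_sep: float, max_tries: int,
                 rng: np.random.Generator):
    """Rejection-sample non-overlapping cell centers; returns geometry rows."""
    h, w = shape
    geoms = []
    for _, row in table.iterrows():
        area_px = float(row["area_px"])
        if bool(row.get("proliferating", False)):
            a = b = math.sqrt(area_px / math.pi)
        else:
            aspect = max(float(row["AspectRatio"]), 1.0)
            a = math.sqrt(area_px * aspect / math.pi)
            b = math.sqrt(area_px / (aspect * math.pi))
        theta = rng.uniform(0.0, math.pi)
        placed = False
        for _ in range(max_tries):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            ok = True
            for g in geoms:
                if math.hypot(cy - g["cy"], cx - g["cx"]) < a + g["a"] + min_sep:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise DensityError(
                f"could not place {len(table)} cells without overlap in a "
                f"{h}x{w} frame; reduce density or enlarge the frame")
        geoms.append({"cell_id": int(row["cell_id"]), "cy": cy, "cx": cx,
                      "a": a, "b": b, "theta": theta,
                      "round": bool(row.get("proliferating", False))})
    return geoms


def render_frame(clone: SyntheticClone, time_h: float, fov_index: int,
                 render: RenderSpec | None = None,
                 ) -> tuple[ImageFrame, LabelMask]:
    """Rasterize one (clone, time, FOV) into a frame + ground-truth mask.

    The mask labels every generated cell 1..n in table order; labels whose
    footprint touches the frame border are listed in
    ``mask.source["border_labels"]``. Deterministic for a given clone
    (its ``render_seed``), time point and FOV.
    """
    render = render or RenderSpec()
    if float(time_h) not in clone.counts:
        raise ValueError(f"time point {time_h} h not in clone {clone.clone_id}")
    table = clone.cells_at(float(time_h))
    table = table.loc[table["fov"] == fov_index]
    h, w = render.image_size
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=clone.render_seed,
        spawn_key=(2, int(time_h), int(fov_index))))

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy0) / h) ** 2 + ((xx - cx0) / w) ** 2
    img = (render.background_level
           - render.vignetting_amplitude * r2 * 4.0
           + rng.normal(0.0, render.background_noise_sd, (h, w)))
    labels = np.zeros((h, w), dtype=np.int32)
    border_labels: list[int] = []

    if len(table):
        geoms = _place_cells(table, (h, w), render.pixel_size,
                             render.min_separation_px,
                             render.max_place_tries, rng)
        for lab, g in enumerate(geoms, start=1):
            pad = int(math.ceil(g["a"])) + 2
            y0, y1 = int(max(0, g["cy"] - pad)), int(min(h, g["cy"] + pad + 1))
            x0, x1 = int(max(0, g["cx"] - pad)), int(min(w, g["cx"] + pad + 1))
            if y0 >= y1 or x0 >= x1:
                continue  # fully clipped; flagged below (no pixels)
            ys = yy[y0:y1, x0:x1] - g["cy"]
            xs = xx[y0:y1, x0:x1] - g["cx"]
            ct, st = math.cos(g["theta"]), math.sin(g["theta"])
            u = xs * ct + ys * st
            v = -xs * st + ys * ct
            inside = (u / g["a"]) ** 2 + (v / g["b"]) ** 2 <= 1.0
            labels[y0:y1, x0:x1][inside] = lab
            if g["round"]:
                tex = rng.normal(render.round_brightness,
                                 render.round_texture_sd, inside.shape)
            else:
                tex = (render.background_level + render.spread_intensity_offset
                       + rng.normal(0.0, render.spread_texture_sd, inside.shape))
            patch = img[y0:y1, x0:x1]
            patch[inside] = tex[inside]
        # ground truth: a cell is border-touching iff it has a pixel on the
        # outermost ring, or rasterized to no pixels at all (clipped away)
        ring = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
        present = np.unique(labels)
        ring_set, present_set = set(ring.tolist()), set(present.tolist())
        border_labels.extend(
            lab for lab in range(1, len(geoms) + 1)
            if lab in ring_set or lab not in present_set)

    frame = ImageFrame(intensity=np.clip(img, 0.0, None),
                       clone_id=clone.clone_id, fov_index=int(fov_index),
                       time_h=float(time_h), pixel_size=render.pixel_size)
    mask = LabelMask(labels, source={
        "clone_id": clone.clone_id, "fov_index": int(fov_index),
        "time_h": float(time_h), "border_labels": border_labels,
        "cell_ids": [g["cell_id"] for g in geoms] if len(table) else []})
    return frame, mask
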