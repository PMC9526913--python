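"""Clone-level time-course morphological profiles.

A profile summarizes a clone's cell population as, for every time point in
the analysis window and every descriptor, the pooled mean and sample SD
over all cells in the selected fields of view. With the full 6-90 h window
(15 time points) and 12 descriptors that is 12 x 2 x 15 = 360 named
parameters per clone; a single time point gives 24.

Parameters are named ``"<Descriptor>_<mean|SD> (<T> h)"`` and ordered
time-major, then descriptor (canonical roster order), then statistic.
Windows always start at 6 h; shortening a window recedes its END in 6-h
steps, so the parameter set of a shorter window is a prefix of a longer
one.

Pooling is over the concatenated cells of the selected FOVs — never a
mean of per-FOV means — and the SD convention is the sample SD (n-1
denominator). Cells flagged degenerate by the descriptor stage are
excluded from all summaries.

Bootstrap resampling draws FOVs *with replacement*: a FOV drawn twice
contributes its cells twice. This is implemented on per-(time, FOV)
sufficient statistics (n, sum, sum of squares), which is exact and makes
repeated resampling cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES, CellRecord

TIME_POINTS_H: tuple[int, ...] = tuple(range(6, 91, 6))
STAT_NAMES: tuple[str, str] = ("mean", "SD")


class InsufficientPopulationError(ValueError):
    """Fewer than two usable cells where a (mean, SD) summary is required."""


class MissingTimePointError(ValueError):
    """A time point required by the analysis window has no cells at all."""


@dataclass
class CloneLabel:
    """A clone's identity and its serial-passage limitation number.

    The serial-passage limitation number is the final passage index reached
    when sub-culturing is repeated until growth arrest, counted from the P3
    primary cell bank — hence it is at least 3. It is the regression
    target throughout.
    """

    clone_id: str
    serial_passage_limit: int
    growth_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.serial_passage_limit < 3:
            raise ValueError(
                "serial_passage_limit counts from the P3 bank and must be >= 3, "
                f"got {self.serial_passage_limit}")


@dataclass
class MorphologicalProfile:
    """One clone's named population-summary vector over a time window."""

    clone_id: str
    names: list[str]
    values: np.ndarray
    window_end_h: int
    fov_count: int
    fov_ids: tuple[int, ...]
    replicate_id: int = 0  # 0 = raw profile, 1..B = bootstrap replicates
    window_start_h: int = 6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.clone_id)


def parameter_names(window_end_h: int,
                    descriptors: Sequence[str] = DESCRIPTOR_NAMES,
                    time_points: Sequence[int] = TIME_POINTS_H) -> list[str]:
    """Ordered parameter names for a 6 h .. ``window_end_h`` window."""
    times = [t for t in time_points if t <= window_end_h]
    if not times:
        raise ValueError(f"window_end_h={window_end_h} excludes every time point")
    return [f"{d}_{s} ({t} h)" for t in times for d in descriptors
            for s in STAT_NAMES]


def records_to_table(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Convert CellRecords to the canonical cell table (column ``fov``)."""
    rows = [r.as_dict() for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["clone_id", "time_h", "fov", "cell_id", "area_px",
                *DESCRIPTOR_NAMES, "degenerate"]
        return pd.DataFrame(columns=cols)
    return df.rename(columns={"fov_index": "fov"})


def _usable(cells: pd.DataFrame) -> pd.DataFrame:
    if "degenerate" in cells.columns:
        return cells.loc[~cells["degenerate"].astype(bool)]
    return cells


def summarize_population(cells: pd.DataFrame | Iterable[CellRecord],
                         descriptors: Sequence[str] = DESCRIPTOR_NAMES,
                         ) -> pd.Series:
    """Pooled (mean, sample SD) of each descriptor over a cell population.

    Returns a Series of 2 x len(descriptors) values named
    ``<Descriptor>_mean`` / ``<Descriptor>_SD`` in roster order.
    """
    if not isinstance(cells, pd.DataFrame):
        cells = records_to_table(cells)
    cells = _usable(cells)
    n = len(cells)
    if n < 2:
        raise InsufficientPopulationError(
            f"need >= 2 usable cells for a (mean, SD) summary, got {n}")
    out: dict[str, float] = {}
    for d in descriptors:
        col = cells[d].to_numpy(dtype=np.float64)
        out[f"{d}_mean"] = float(col.mean())
        out[f"{d}_SD"] = float(col.std(ddof=1))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# sufficient statistics: exact pooled summaries under FOV multiplicity
# ---------------------------------------------------------------------------

def _suffstats(cells: pd.DataFrame,
               descriptors: Sequence[str]) -> pd.DataFrame:
    """Per-(time_h, fov) n / sum / sum-of-squares for each descriptor."""
    cells = _usable(cells)
    keys = [cells["time_h"], cells["fov"]]
    vals = cells[list(descriptors)]
    s1 = vals.groupby(keys, sort=True).sum()
    s2 = (vals ** 2).groupby(keys, sort=True).sum()
    parts = {("n", ""): cells.groupby(keys, sort=True).size()}
    for d in descriptors:
        parts[("s1", d)] = s1[d]
        parts[("s2", d)] = s2[d]
    return pd.DataFrame(parts)


def _pooled_from_stats(stats: pd.DataFrame, time_h: float,
                       fov_multiplicity: Mapping[int, int],
                       descriptors: Sequence[str],
                       context: str) -> list[float]:
    try:
        at_t = stats.loc[time_h]
    except KeyError:
        raise MissingTimePointError(
            f"no cells at time point {time_h} h ({context})") from None
    fovs_here = set(at_t.index.tolist())
    use = [(f, m) for f, m in fov_multiplicity.items()
           if m and f in fovs_here]
    if use:
        fovs = [f for f, _ in use]
        w = np.asarray([m for _, m in use], dtype=np.float64)
        sub = at_t.loc[fovs]
        n_tot = float(w @ sub[("n", "")].to_numpy(dtype=np.float64))
    else:
        n_tot = 0.0
    if n_tot < 2:
        raise InsufficientPopulationError(
            f"{int(n_tot)} usable cell(s) at {time_h} h in the drawn FOVs "
            f"({context})")
    vals: list[float] = []
    for d in descriptors:
        s1 = float(w @ sub[("s1", d)].to_numpy(dtype=np.float64))
        s2 = float(w @ sub[("s2", d)].to_numpy(dtype=np.float64))
        mean = s1 / n_tot
        var = max(s2 - n_tot * mean * mean, 0.0) / (n_tot - 1.0)
        vals.extend((mean, float(np.sqrt(var))))
    return vals


def _single_clone(cells: pd.DataFrame) -> str:
    ids = cells["clone_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected cells of exactly one clone, got {list(ids)}")
    return str(ids[0])


def build_profile(cells: pd.DataFrame, window_end_h: int,
                  fov_ids: Sequence[int],
                  descriptors: Sequence[str] = DESCRIPTOR_NAMES,
                  time_points: Sequence[int] = TIME_POINTS_H,
                  replicate_id: int = 0) -> MorphologicalProfile:
    """Build one clone's profile from the cells of the selected FOVs.

    ``fov_ids`` may contain repeats (bootstrap draws); each occurrence
    contributes the FOV's cells once more to the pooled summary.
    """
    if window_end_h not in time_points:
        raise ValueError(
            f"window_end_h={window_end_h} not on the acquisition grid "
            f"{tuple(time_points)}")
    fov_ids = list(int(f) for f in fov_ids)
    if not fov_ids:
        raise ValueError("fov_ids must be a nonempty selection")
    clone_id = _single_clone(cells)
    mult: dict[int, int] = {}
    for f in fov_ids:
        mult[f] = mult.get(f, 0) + 1
    stats = _suffstats(cells, descriptors)
    times = [t for t in time_points if t <= window_end_h]
    values: list[float] = []
    for t in times:
        values.extend(_pooled_from_stats(
            stats, float(t), mult, descriptors, context=f"clone {clone_id}"))
    return MorphologicalProfile(
        clone_id=clone_id,
        names=parameter_names(window_end_h, descriptors, time_points),
        values=np.asarray(values),
        window_end_h=int(window_end_h),
        fov_count=len(set(fov_ids)) if replicate_id == 0 else len(fov_ids),
        fov_ids=tuple(fov_ids),
        replicate_id=replicate_id,
    )


def subsample_fovs(available: Sequence[int], k: int,
                   seed: int | np.random.Generator) -> list[int]:
    """Draw ``k`` distinct FOV ids uniformly without replacement."""
    available = sorted(int(f) for f in set(available))
    if not 1 <= k <= len(available):
        raise ValueError(f"k={k} out of range 1..{len(available)}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return sorted(rng.choice(available, size=k, replace=False).tolist())


def bootstrap_profiles(cells: pd.DataFrame, window_end_h: int, k: int,
                       B: int, seed: int,
                       descriptors: Sequence[str] = DESCRIPTOR_NAMES,
                       time_points: Sequence[int] = TIME_POINTS_H,
                       ) -> list[MorphologicalProfile]:
    """B bootstrap profiles per clone, each from k FOVs drawn WITH replacement.

    With 15 clones and B = 50 this expands the dataset from 15 to 750
    profiles. Replicates carry ``replicate_id`` 1..B.
    """
    if B < 1 or k < 1:
        raise ValueError("B and k must be >= 1")
    rng = np.random.default_rng(seed)
    profiles: list[MorphologicalProfile] = []
    for clone_id, sub in cells.groupby("clone_id", sort=True):
        available = sorted(sub["fov"].unique().tolist())
        stats = _suffstats(sub, descriptors)
        times = [t for t in time_points if t <= window_end_h]
        if window_end_h not in time_points:
            raise ValueError(f"window_end_h={window_end_h} not on grid")
        names = parameter_names(window_end_h, descriptors, time_points)
        for b in range(1, B + 1):
            draw = rng.choice(available, size=k, replace=True)
            mult: dict[int, int] = {}
            for f in draw.tolist():
                mult[int(f)] = mult.get(int(f), 0) + 1
            values: list[float] = []
            for t in times:
                values.extend(_pooled_from_stats(
                    stats, float(t), mult, descriptors,
                    context=f"clone {clone_id}, bootstrap replicate {b}"))
            profiles.append(MorphologicalProfile(
                clone_id=str(clone_id), names=names,
                values=np.asarray(values), window_end_h=int(window_end_h),
                fov_count=k, fov_ids=tuple(int(f) for f in draw),
                replicate_id=b))
    return profiles


def growth_rate(counts: Mapping[float, int] | pd.Series,
                start_h: float = 6.0, end_h: float = 90.0) -> float:
    """Fold-change of the cell count between the window's first and last points."""
    counts = dict(counts)
    for t in (start_h, end_h):
        if t not in counts:
            raise ValueError(f"no cell count at {t} h")
    if counts[start_h] <= 0:
        raise ZeroDivisionError(
            f"zero cell count at {start_h} h: growth rate undefined")
    return float(counts[end_h]) / float(counts[start_h])


@dataclass
class CohortDataset:
    """Aligned (profile, label) pairs ready for model fitting."""

    profiles: list[MorphologicalProfile]
    labels: dict[str, CloneLabel]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("empty dataset")
        names0 = self.profiles[0].names
        for p in self.profiles:
            if p.names != names0:
                raise ValueError(
                    f"profile {p.clone_id} has mismatched parameter names")
            if p.clone_id not in self.labels:
                raise ValueError(f"no label for clone {p.clone_id}")

    @property
    def parameter_names(self) -> list[str]:
        return self.profiles[0].names

    @property
    def is_bootstrap(self) -> bool:
        return any(p.replicate_id > 0 for p in self.profiles)

    def to_matrices(self) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """Return (X, y, groups): rows = clone x replicate, groups = clone ids."""
        X = pd.DataFrame([p.values for p in self.profiles],
                         columns=self.parameter_names)
        y = np.asarray([self.labels[p.clone_id].serial_passage_limit
                        for p in self.profiles], dtype=np.float64)
        groups = np.asarray([p.clone_id for p in self.profiles], dtype=object)
        return X, y, groups

    def clone_ids(self) -> list[str]:
        return sorted({p.clone_id for p in self.profiles})
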