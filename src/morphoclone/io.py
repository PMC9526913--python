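"""Reading and writing the pipeline's file formats.

Cell tables, label tables, profile tables and grid results are plain
delimited files (CSV); frames and masks are 8/16-bit grayscale TIFF (or
PNG for frames). A JSON sidecar written next to a simulated cohort echoes
the full generating spec and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import io as skio

from .profiling import MorphologicalProfile
from .segmentation import DEFAULT_PIXEL_SIZE_UM, ImageFrame, LabelMask
from .synthetic import RenderSpec, SyntheticClone, SyntheticCohortSpec, \
    cohort_labels, render_frame

_META_COLS = ["clone_id", "replicate_id", "window_end_h", "fov_count"]


def write_frame(frame: ImageFrame, path: str | Path) -> None:
    """Write a frame as 16-bit grayscale TIFF (intensities rounded)."""
    arr = np.clip(np.rint(frame.intensity), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_frame(path: str | Path, clone_id: str = "", fov_index: int = 0,
               time_h: float = 6.0,
               pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> ImageFrame:
    """Read an 8/16-bit grayscale TIFF or PNG frame."""
    arr = skio.imread(str(path))
    if arr.ndim == 3:  # grayscale stored with a trivial channel axis
        arr = arr[..., 0]
    name = Path(path).stem
    return ImageFrame(intensity=arr.astype(np.float64),
                      clone_id=clone_id or name, fov_index=fov_index,
                      time_h=time_h, pixel_size=pixel_size)


def write_mask(mask: LabelMask, path: str | Path) -> None:
    if mask.n_labels > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def read_mask(path: str | Path) -> LabelMask:
    return LabelMask(tifffile.imread(str(path)).astype(np.int32))


def frame_filename(clone_id: str, time_h: float, fov_index: int) -> str:
    return f"{clone_id}_t{int(time_h):02d}_fov{int(fov_index):02d}.tif"


def write_cohort(clones: Sequence[SyntheticClone], outdir: str | Path,
                 spec: SyntheticCohortSpec | None = None,
                 render: bool = False,
                 render_spec: RenderSpec | None = None,
                 render_fovs: int = 2,
                 render_times: Sequence[float] | None = None) -> Path:
    """Write a cohort: per-clone cell tables, labels, spec sidecar, frames.

    Rendering every (time, FOV) of a full cohort produces tens of
    thousands of frames, so by default only the first ``render_fovs``
    FOVs of each requested time point are rasterized.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for clone in clones:
        clone.cells.to_csv(outdir / f"{clone.clone_id}.csv", index=False)
    cohort_labels(clones).to_csv(outdir / "labels.csv", index=False)
    if spec is not None:
        (outdir / "spec.json").write_text(
            json.dumps(spec.as_jsonable(), indent=2))
    if render:
        rs = render_spec or RenderSpec()
        fdir = outdir / "frames"
        mdir = outdir / "masks"
        fdir.mkdir(exist_ok=True)
        mdir.mkdir(exist_ok=True)
        for clone in clones:
            times = render_times if render_times is not None \
                else sorted(clone.counts)
            for t in times:
                for fov in range(render_fovs):
                    frame, mask = render_frame(clone, t, fov, rs)
                    name = frame_filename(clone.clone_id, t, fov)
                    write_frame(frame, fdir / name)
                    write_mask(mask, mdir / name)
    return outdir


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read one cell table, or concatenate every per-clone table in a dir."""
    path = Path(path)
    if path.is_dir():
        parts = [pd.read_csv(p) for p in sorted(path.glob("*.csv"))
                 if p.name != "labels.csv"]
        if not parts:
            raise FileNotFoundError(f"no cell tables in {path}")
        return pd.concat(parts, ignore_index=True)
    return pd.read_csv(path)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "labels.csv"
                       if Path(path).is_dir() else path)


def profiles_to_frame(profiles: Sequence[MorphologicalProfile]) -> pd.DataFrame:
    """Wide profile table: metadata columns then named parameters."""
    rows = []
    for p in profiles:
        row = {"clone_id": p.clone_id, "replicate_id": p.replicate_id,
               "window_end_h": p.window_end_h, "fov_count": p.fov_count}
        row.update(dict(zip(p.names, p.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[MorphologicalProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    param_cols = [c for c in df.columns if c not in _META_COLS]
    out = []
    for _, r in df.iterrows():
        out.append(MorphologicalProfile(
            clone_id=str(r["clone_id"]),
            names=param_cols,
            values=r[param_cols].to_numpy(dtype=np.float64),
            window_end_h=int(r["window_end_h"]),
            fov_count=int(r["fov_count"]),
            fov_ids=(),
            replicate_id=int(r.get("replicate_id", 0))))
    return out
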