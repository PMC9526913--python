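"""Per-cell morphological descriptors.

Twelve descriptors are measured for every segmented cell region:

===============  ==========  ====================================================
name             units       definition
===============  ==========  ====================================================
Area             um^2        pixel count x pixel_size^2
Perimeter        um          contour length (chain-code approximation)
Length           um          major axis of the best-fit ellipse
Breadth          um          minor axis of the best-fit ellipse
AspectRatio      --          Length / Breadth (>= 1)
Compactness      --          Perimeter^2 / (4 pi Area); 1 for a disk
Roundness        --          4 pi Area / Perimeter^2 = 1 / Compactness
Solidity         --          Area / convex-hull area
IntensityMean    a.u.        mean intensity over the in-mask pixels
IntensitySD      a.u.        SD of intensity over the in-mask pixels
Correlation      --          GLCM correlation of the masked intensity patch
Energy           --          GLCM energy (angular second moment) of the patch
===============  ==========  ====================================================

Shape descriptors are computed on the binary region; texture and intensity
descriptors on the masked intensity patch only (pixels outside the region
never enter the co-occurrence counts, which is why the GLCM is accumulated
here rather than on a rectangular crop). Length/Breadth use the best-fit
ellipse rather than Feret diameters; ``length_mode="feret"`` switches to
the maximum Feret diameter for users who prefer that convention.

Degenerate regions (a single pixel, or zero intensity variance) get the
defined degenerate texture values Energy = 1, Correlation = 0 and are
flagged via ``CellRecord.degenerate`` so callers can filter them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage import measure

from .segmentation import ImageFrame, LabelMask

#: canonical descriptor order used throughout profiles and tables
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Area", "Perimeter", "Length", "Breadth", "AspectRatio", "Compactness",
    "Roundness", "Solidity", "IntensityMean", "IntensitySD",
    "Correlation", "Energy",
)

#: GLCM offsets (dr, dc) for angles 0, 45, 90, 135 degrees at distance 1
_DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class GlcmParams:
    """Gray-level co-occurrence matrix parameters.

    Intensities are quantized to ``levels`` gray levels over the per-patch
    min-max range; the matrix is accumulated symmetrically over all
    ``offsets`` (restricted to in-mask pixel pairs), normalized per offset
    and averaged.
    """

    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = _DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.offsets) == 0:
            raise ValueError("need at least one offset")


@dataclass
class CellRecord:
    """One segmented cell's 12-descriptor vector with provenance."""

    clone_id: str
    time_h: float
    fov_index: int
    cell_id: int
    area_px: int
    Area: float
    Perimeter: float
    Length: float
    Breadth: float
    AspectRatio: float
    Compactness: float
    Roundness: float
    Solidity: float
    IntensityMean: float
    IntensitySD: float
    Correlation: float
    Energy: float
    degenerate: bool = field(default=False)

    def as_dict(self) -> dict:
        return asdict(self)


def quantize_patch(values: np.ndarray, levels: int) -> np.ndarray:
    """Quantize intensities to ``levels`` bins over their min-max range."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.intp)
    q = ((values - vmin) / (vmax - vmin) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def cooccurrence_matrix(patch: np.ndarray, mask: np.ndarray,
                        glcm: GlcmParams | None = None) -> np.ndarray:
    """Offset-averaged normalized co-occurrence matrix of in-mask pixels.

    Only pairs whose two pixels both lie inside ``mask`` are counted. With
    ``symmetric`` each pair is counted in both orders.
    """
    glcm = glcm or GlcmParams()
    patch = np.asarray(patch, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if patch.shape != mask.shape:
        raise ValueError("patch and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    # quantization range driven by in-mask values only
    vals = patch[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    q = np.zeros(patch.shape, dtype=np.intp)
    if vmax > vmin:
        qi = np.clip((patch - vmin) / (vmax - vmin) * glcm.levels, 0, None)
        q[mask] = np.minimum(qi[mask].astype(np.intp), glcm.levels - 1)

    L = glcm.levels
    mats = []
    n_pairs_total = 0
    for dr, dc in glcm.offsets:
        h, w = q.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if not valid.any():
            continue
        i, j = a[valid], b[valid]
        mat = np.zeros((L, L), dtype=np.float64)
        np.add.at(mat, (i, j), 1.0)
        if glcm.symmetric:
            mat = mat + mat.T
        n_pairs_total += int(valid.sum())
        if glcm.normalize:
            mat /= mat.sum()
        mats.append(mat)
    if not mats:
        raise ValueError("no in-mask pixel pairs at any offset")
    return np.mean(mats, axis=0)


def glcm_features(patch: np.ndarray, mask: np.ndarray | None = None,
                  glcm: GlcmParams | None = None) -> tuple[float, float, bool]:
    """GLCM (Correlation, Energy) of a masked intensity patch.

    Returns ``(correlation, energy, degenerate)``; ``degenerate`` is True
    when either gray-level marginal has zero variance, in which case
    Correlation is the defined degenerate value 0.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if mask is None:
        mask = np.ones(patch.shape, dtype=bool)
    P = cooccurrence_matrix(patch, mask, glcm)
    L = P.shape[0]
    idx = np.arange(L, dtype=np.float64)
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(idx @ pi)
    mu_j = float(idx @ pj)
    var_i = float(((idx - mu_i) ** 2) @ pi)
    var_j = float(((idx - mu_j) ** 2) @ pj)
    energy = float((P * P).sum())
    if var_i <= 0 or var_j <= 0:
        return 0.0, energy, True
    corr = float(((idx[:, None] - mu_i) * (idx[None, :] - mu_j) * P).sum()
                 / np.sqrt(var_i * var_j))
    return corr, energy, False


def _feret_diameter(region) -> float:
    try:
        return float(region.feret_diameter_max)
    except Exception:
        return float(region.axis_major_length)


def measure_cell(frame: ImageFrame, mask: LabelMask, label: int,
                 glcm: GlcmParams | None = None,
                 length_mode: str = "ellipse") -> CellRecord:
    """Measure the 12 descriptors of one labelled region."""
    if label < 1 or label > mask.n_labels:
        raise ValueError(f"label {label} not present in mask (1..{mask.n_labels})")
    if frame.shape != mask.shape:
        raise ValueError(f"frame {frame.shape} and mask {mask.shape} misaligned")
    region_mask = mask.labels == label
    if not region_mask.any():
        raise ValueError(f"label {label} not present in mask")
    props = measure.regionprops(region_mask.astype(np.uint8),
                                intensity_image=frame.intensity)[0]
    ps = frame.pixel_size
    area_px = int(props.area)
    area = area_px * ps * ps
    # Crofton estimate: markedly less digitization/rotation bias than the
    # chain-code perimeter (a digital disk comes out within ~2% of 2*pi*r)
    perim = float(props.perimeter_crofton) * ps
    if length_mode == "feret":
        length = _feret_diameter(props) * ps
        breadth = float(props.axis_minor_length) * ps
    elif length_mode == "ellipse":
        length = float(props.axis_major_length) * ps
        breadth = float(props.axis_minor_length) * ps
    else:
        raise ValueError(f"unknown length_mode {length_mode!r}")

    vals = frame.intensity[region_mask]
    imean = float(vals.mean())
    isd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    degenerate = area_px < 2 or np.ptp(vals) == 0
    if degenerate:
        corr, energy = 0.0, 1.0
    else:
        sl = props.slice
        corr, energy, tex_degen = glcm_features(
            frame.intensity[sl], region_mask[sl], glcm)
        degenerate = degenerate or tex_degen

    if perim > 0 and area > 0:
        compact = perim * perim / (4.0 * np.pi * area)
        roundness = 1.0 / compact
    else:  # single-pixel regions have zero chain-code perimeter
        compact, roundness = 1.0, 1.0
        degenerate = True
    if breadth <= 0:
        breadth = ps  # 1-px-wide region: minor axis degenerate
        degenerate = True
    aspect = max(length, breadth) / breadth

    return CellRecord(
        clone_id=frame.clone_id, time_h=frame.time_h,
        fov_index=frame.fov_index, cell_id=int(label),
        area_px=area_px, Area=area, Perimeter=perim,
        Length=max(length, breadth), Breadth=breadth, AspectRatio=aspect,
        Compactness=compact, Roundness=roundness,
        Solidity=float(props.solidity), IntensityMean=imean, IntensitySD=isd,
        Correlation=corr, Energy=energy, degenerate=bool(degenerate),
    )


def measure_frame(frame: ImageFrame, mask: LabelMask,
                  glcm: GlcmParams | None = None,
                  length_mode: str = "ellipse") -> list[CellRecord]:
    """Measure every labelled region of a frame, in label order."""
    if frame.shape != mask.shape:
        raise ValueError(f"frame {frame.shape} and mask {mask.shape} misaligned")
    return [measure_cell(frame, mask, lab, glcm, length_mode)
            for lab in range(1, mask.n_labels + 1)]
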