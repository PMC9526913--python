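"""Shared fixtures: small synthetic cohorts and rendered frames.

Everything is generated at test time from fixed seeds; fixtures are
session-scoped because cohort generation and rendering dominate test
runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import morphoclone as mc


@pytest.fixture(scope="session")
def small_spec() -> mc.SyntheticCohortSpec:
    """15 clones at reduced per-well cell counts: fast but full-structure."""
    return mc.SyntheticCohortSpec(
        n_clones=15, seed=42, cells_per_well_range=(300, 800), n_fovs=16)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return mc.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_cells(small_cohort):
    return mc.cohort_cells(small_cohort)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return mc.cohort_labels(small_cohort)


@pytest.fixture(scope="session")
def render_clone() -> mc.SyntheticClone:
    """One clone whose FOVs hold ~20 cells each (renderable densities)."""
    spec = mc.SyntheticCohortSpec(
        n_clones=1, seed=5, cells_per_well_range=(300, 400), n_fovs=16)
    return mc.generate_cohort(spec)[0]


@pytest.fixture(scope="session")
def rendered_pair(render_clone):
    """A rendered frame plus its ground-truth mask (default RenderSpec)."""
    return mc.render_frame(render_clone, 6.0, 0)


def _best_iou(region: np.ndarray, other_labels: np.ndarray) -> float:
    counts = np.bincount(other_labels[region].ravel())
    counts[0] = 0
    if counts.sum() == 0:
        return 0.0
    best = int(counts.argmax())
    m = other_labels == best
    return float((region & m).sum() / (region | m).sum())


def iou_recall(gt: mc.LabelMask, seg: mc.LabelMask,
               min_iou: float = 0.5) -> tuple[float, float, int]:
    """(recall, precision, n_non_border_gt) at the IoU threshold.

    Recall counts non-border ground-truth cells recovered by some
    segmented region; precision counts segmented regions matching *any*
    ground-truth cell (a border cell legitimately survives segmentation
    when erosion detaches it from the frame ring).
    """
    border = set(gt.source.get("border_labels", []))
    non_border = [l for l in range(1, gt.n_labels + 1) if l not in border]
    hits = sum(1 for lab in non_border
               if _best_iou(gt.labels == lab, seg.labels) >= min_iou)
    matched = sum(1 for s in range(1, seg.n_labels + 1)
                  if _best_iou(seg.labels == s, gt.labels) >= min_iou)
    recall = hits / max(len(non_border), 1)
    precision = matched / max(seg.n_labels, 1)
    return recall, precision, len(non_border)
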