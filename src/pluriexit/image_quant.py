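"""Per-cell nuclear/cytoplasmic intensity quantification.

Replicates an automated immunofluorescence readout of subcellular protein
relocalization: nuclei are segmented from a DNA (DAPI) channel, cell bodies
from a whole-cell channel seeded by the nuclei, and for every cell the mean
target-channel intensity is measured over the nucleus and over the
cytoplasm (cell minus nucleus); the per-cell nuclear/cytoplasmic (N/C)
ratio is the readout.  Groups of cells (e.g. knockdown vs control, 2i vs
released) are compared by a two-sample Student's t-test on the pooled
per-cell ratios, with box-and-whisker summaries.

Segmentation is intentionally classical and fully parameterized: global
Otsu threshold on the DNA channel, connected components with a minimum
area, Otsu threshold on the cell channel, and a nucleus-seeded watershed of
the cell foreground.  Cells touching the image border are excluded because
their truncated cytoplasm biases the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.segmentation import watershed


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation parameters, all recorded in outputs for provenance."""

    min_nucleus_area: int = 20  # px; rejects debris below this size
    exclude_border: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Segmentation:
    """Label images of the segmentation: ``nuclei`` and ``cells``.

    Labels are aligned: nucleus *k* lies inside cell *k*.  ``params``
    records the configuration that produced the masks.
    """

    nuclei: np.ndarray
    cells: np.ndarray
    params: dict

    @property
    def n_cells(self) -> int:
        return int(self.nuclei.max())


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def segment(
    dna: np.ndarray,
    cell: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> Segmentation:
    """Segment nuclei from the DNA channel and cells from the cell channel.

    Nuclei: Otsu threshold, connected components, minimum-area filter.
    Cells: Otsu foreground, watershed seeded with the nucleus labels —
    every retained cell therefore contains exactly one nucleus, and cells
    without a detectable nucleus are never produced.  Border-touching
    cells are dropped (with their nuclei) when ``cfg.exclude_border``.

    Returns an empty segmentation with a warning when no nuclei are found
    (e.g. a blank image).
    """
    cfg = cfg or SegmentationConfig()
    dna = np.asarray(dna, dtype=float)
    cell = np.asarray(cell, dtype=float)
    if dna.shape != cell.shape:
        raise ValueError(f"channel shapes differ: {dna.shape} vs {cell.shape}")
    empty = Segmentation(
        nuclei=np.zeros(dna.shape, dtype=int), cells=np.zeros(dna.shape, dtype=int), params=cfg.as_dict()
    )
    if np.ptp(dna) == 0:
        warnings.warn("no nuclei found: DNA channel is constant", stacklevel=2)
        return empty
    nuc_mask = dna > threshold_otsu(dna)
    labels = label(nuc_mask)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= cfg.min_nucleus_area)
    keep = keep[keep != 0]
    if keep.size == 0:
        warnings.warn("no nuclei found above the minimum area", stacklevel=2)
        return empty

    relabel = np.zeros(sizes.size, dtype=int)
    relabel[keep] = np.arange(1, keep.size + 1)
    nuclei = relabel[labels]

    if np.ptp(cell) == 0:
        cell_fg = nuclei > 0
    else:
        cell_fg = cell > threshold_otsu(cell)
    cell_fg |= nuclei > 0  # a nucleus is always part of its cell
    distance = ndimage.distance_transform_edt(cell_fg)
    cells = watershed(-distance, markers=nuclei, mask=cell_fg)

    drop = []
    for k in range(1, keep.size + 1):
        if cfg.exclude_border and _touches_border(cells == k):
            drop.append(k)
    if drop:
        for k in drop:
            cells[cells == k] = 0
            nuclei[nuclei == k] = 0
    # compact labels after drops, keeping nucleus/cell alignment
    survivors = sorted(set(np.unique(nuclei)) - {0})
    mapping = np.zeros(int(nuclei.max()) + 1, dtype=int)
    for new, old in enumerate(survivors, start=1):
        mapping[old] = new
    nuclei = mapping[nuclei]
    cells = mapping[cells]
    return Segmentation(nuclei=nuclei, cells=cells, params=cfg.as_dict())


def measure_ratio(seg: Segmentation, target: np.ndarray) -> pd.DataFrame:
    """Per-cell nuclear and cytoplasmic mean target intensity and their ratio.

    Cytoplasm is the cell mask minus the nucleus mask.  Cells whose
    cytoplasm is empty are dropped with a warning.  Returns one row per
    cell: ``cell_id``, ``nuclear_mean``, ``cytoplasmic_mean``, ``ratio``,
    ``nucleus_area``, ``cytoplasm_area``.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != seg.nuclei.shape:
        raise ValueError("target channel shape differs from segmentation")
    rows = []
    for k in range(1, seg.n_cells + 1):
        nuc = seg.nuclei == k
        cyto = (seg.cells == k) & ~nuc
        n_area = int(nuc.sum())
        c_area = int(cyto.sum())
        if c_area == 0:
            warnings.warn(f"cell {k} has empty cytoplasm; dropped", stacklevel=2)
            continue
        n_mean = float(target[nuc].mean())
        c_mean = float(target[cyto].mean())
        rows.append(
            {
                "cell_id": k,
                "nuclear_mean": n_mean,
                "cytoplasmic_mean": c_mean,
                "ratio": n_mean / c_mean if c_mean > 0 else float("nan"),
                "nucleus_area": n_area,
                "cytoplasm_area": c_area,
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "nuclear_mean", "cytoplasmic_mean", "ratio", "nucleus_area", "cytoplasm_area"]
    )


def quantify(
    dna: np.ndarray,
    cell: np.ndarray,
    target: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Segment and measure in one call; see :func:`segment` and :func:`measure_ratio`."""
    return measure_ratio(segment(dna, cell, cfg), target)


def _five_number(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "n": int(x.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
    }


def compare_groups(
    ratios_a: np.ndarray,
    ratios_b: np.ndarray,
    *,
    equal_var: bool = True,
) -> dict:
    """Box-and-whisker summaries and a two-sided two-sample t-test.

    Whiskers follow the Tukey convention (most extreme points within
    1.5 x IQR of the quartiles).  ``equal_var=True`` is the classical
    Student's test; pass False for Welch.  Requires n >= 2 per group.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 cells per group, got {a.size} and {b.size}")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "group_a": _five_number(a),
        "group_b": _five_number(b),
        "t_statistic": float(t),
        "p_value": float(p),
        "test": "student" if equal_var else "welch",
        "whisker_convention": "1.5*IQR",
    }
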