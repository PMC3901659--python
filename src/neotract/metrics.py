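"""Tract micro/macrostructure metrics: fiber count, voxel count, mean scalars.

A segmented tract is summarized by six numbers: the number of surviving
streamlines ("fibers"), the number of unique voxels those streamlines
traverse (a macrostructural volume proxy), and the mean FA/MD/AD/RD over
that voxel set.  Voxel traversal is computed by exact segment/boundary
marching, not sampling, so counts are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tensor import ScalarMaps
from .tracking import Streamline, world_to_grid

#: Column order of the metrics CSV consumed by the reliability module.
METRICS_COLUMNS = ["tract", "n_fibers", "n_voxels",
                   "mean_fa", "mean_md", "mean_ad", "mean_rd"]


@dataclass
class TractMetrics:
    tract_name: str
    n_fibers: int
    n_voxels: int
    mean_fa: float
    mean_md: float
    mean_ad: float
    mean_rd: float

    def as_row(self) -> dict:
        return {"tract": self.tract_name, "n_fibers": self.n_fibers,
                "n_voxels": self.n_voxels, "mean_fa": self.mean_fa,
                "mean_md": self.mean_md, "mean_ad": self.mean_ad,
                "mean_rd": self.mean_rd}


def _segment_voxels(a: np.ndarray, b: np.ndarray,
                    shape: tuple[int, int, int]) -> set:
    """Voxels traversed by the segment a->b (grid space), by exact marching.

    Splits [0, 1] at every integer-plane crossing and assigns each
    sub-interval's midpoint to its containing voxel, which is exact for
    straight segments and robust to endpoints lying on voxel boundaries.
    """
    d = b - a
    ts = {0.0, 1.0}
    for axis in range(3):
        if abs(d[axis]) < 1e-12:
            continue
        lo, hi = sorted((a[axis], b[axis]))
        for k in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
            t = (k - a[axis]) / d[axis]
            if 0.0 < t < 1.0:
                ts.add(float(t))
    out = set()
    ts = sorted(ts)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        mid = a + 0.5 * (t0 + t1) * d
        vox = np.floor(mid).astype(int)
        if ((0 <= vox).all() and (vox < np.array(shape)).all()):
            out.add(tuple(int(c) for c in vox))
    return out


def voxelize_streamline(streamline: Streamline, affine: np.ndarray,
                        shape: tuple[int, int, int]) -> frozenset:
    """The set of voxel indices a single streamline passes through."""
    pts = world_to_grid(streamline.points, affine)
    out = set()
    for a, b in zip(pts[:-1], pts[1:]):
        out |= _segment_voxels(a, b, shape)
    if not out and len(pts):
        vox = np.floor(pts[0]).astype(int)
        if ((0 <= vox).all() and (vox < np.array(shape)).all()):
            out.add(tuple(int(c) for c in vox))
    return frozenset(out)


def voxelize(streamlines, affine: np.ndarray,
             shape: tuple[int, int, int]) -> set:
    """Union of traversed voxels over a collection of streamlines."""
    out = set()
    for sl in streamlines:
        out |= voxelize_streamline(sl, affine, shape)
    return out


def compute_metrics(segmentation, scalar_maps: ScalarMaps) -> TractMetrics:
    """Summarize a tract segmentation over the scalar maps' grid.

    Means are voxel-weighted: each traversed voxel contributes once,
    regardless of how many streamlines or points visit it.  An empty
    segmentation yields zero counts and NaN means (flagged, not an error).
    """
    shape = scalar_maps.fa.shape
    vox = voxelize(segmentation.streamlines, scalar_maps.affine, shape)
    n_fibers = len(segmentation.streamlines)
    if not vox:
        return TractMetrics(segmentation.tract_name, n_fibers, 0,
                            float("nan"), float("nan"),
                            float("nan"), float("nan"))
    idx = tuple(np.array(sorted(vox)).T)
    return TractMetrics(
        tract_name=segmentation.tract_name,
        n_fibers=n_fibers,
        n_voxels=len(vox),
        mean_fa=float(scalar_maps.fa[idx].mean()),
        mean_md=float(scalar_maps.md[idx].mean()),
        mean_ad=float(scalar_maps.ad[idx].mean()),
        mean_rd=float(scalar_maps.rd[idx].mean()),
    )


def metrics_table(metrics: list[TractMetrics], **extra_columns) -> pd.DataFrame:
    """Stack per-tract metrics into the CSV schema, with optional id columns
    (subject, rater, repeat) prepended."""
    df = pd.DataFrame([m.as_row() for m in metrics], columns=METRICS_COLUMNS)
    for name, value in reversed(extra_columns.items()):
        df.insert(0, name, value)
    return df
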