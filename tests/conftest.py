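import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from budprofiler.ellipse import ContourSet
from budprofiler.segmentation import SegmentationResult


def make_disk_contour(centers, r=15.0, shape=(64, 84), thickness=5.0):
    """Contour band (pixels within `thickness` of background) of ideal disks."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    fg = np.zeros(shape, bool)
    for cy, cx in centers:
        fg |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    d = distance_transform_edt(fg)
    band = fg & (d <= thickness) & (d > 0)
    return ContourSet(pixels=np.argwhere(band)), ~fg, fg


def deterministic_segmentation(fg_mask: np.ndarray) -> SegmentationResult:
    """Posterior in {0,1} with identity transitions (deterministic limit)."""
    return SegmentationResult(
        foreground_prob=fg_mask.astype(float),
        means=np.array([0.0, 1.0]),
        sds=np.array([1.0, 1.0]),
        transmat=np.eye(2),
    )


def dijkstra_oracle(bg_mask: np.ndarray) -> np.ndarray:
    """Brute-force shortest-path distance to background (border counts as
    background) under the axial/diagonal/knight move set."""
    import heapq

    h, w = bg_mask.shape
    bg = bg_mask.copy()
    bg[0, :] = bg[-1, :] = True
    bg[:, 0] = bg[:, -1] = True
    moves = (
        [(dr, dc, 1.0) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
        + [(dr, dc, np.sqrt(2.0)) for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1))]
        + [(dr, dc, np.sqrt(5.0)) for dr, dc in (
            (-2, -1), (-2, 1), (2, -1), (2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2))]
    )
    dist = np.full((h, w), np.inf)
    dist[bg] = 0.0
    heap = [(0.0, r, c) for r, c in zip(*np.nonzero(bg))]
    heapq.heapify(heap)
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, s in moves:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and d + s < dist[rr, cc]:
                dist[rr, cc] = d + s
                heapq.heappush(heap, (d + s, rr, cc))
    return dist


@pytest.fixture(scope="session")
def rendered_scene():
    """One rendered default scene with its identification products."""
    import budprofiler as bp
    from budprofiler.config import PipelineConfig
    from budprofiler.pipeline import identify_cells

    cfg = bp.synthetic.SceneConfig(seed=7, height=224, width=224, n_cells=18,
                                   bud_fraction=0.5)
    mic, truth = bp.synthetic.simulate_micrograph(cfg)
    img = identify_cells(mic, PipelineConfig(), seed=0, truth=truth)
    return img
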