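"""Interpretable per-cell protein-expression features.

Six measurements per cell: a size-normalized GFP/RFP intensity ratio and
five "morphological distances".  Treating the (background-corrected)
intensity of a channel as a probability distribution over the cell's
pixels, the expected geometric distance of a protein to a landmark — the
cell centre, the channel's own mass centre, the cell periphery (via the
edge-distance map), the bud neck, or to another protein molecule — is
computed for the GFP channel, normalized by the same expectation for the
constitutive RFP marker, and reported as a log ratio.  A log ratio of zero
means the tagged protein is spatially distributed like the whole-cell
marker; negative values mean it concentrates at the landmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .segmentation import EdgeDistanceMap

__all__ = [
    "RfpSizeModel",
    "FeatureVector",
    "RupturedCellError",
    "fit_rfp_size_model",
    "intensity_ratio",
    "morphological_distances",
    "FEATURE_NAMES",
    "DISTANCE_NAMES",
]

DISTANCE_NAMES = (
    "d_between_proteins",
    "d_mass_center",
    "d_cell_center",
    "d_periphery",
    "d_neck",
)
FEATURE_NAMES = ("intensity_ratio",) + DISTANCE_NAMES


class RupturedCellError(ValueError):
    """Zero total RFP inside a cell: the ruptured-cell signature."""


@dataclass
class RfpSizeModel:
    """Expected mean RFP level as a function of cell area.

    Three linear segments, continuous at two interior breakpoints
    (hinge parameterisation: m(x) = c0 + c1 x + c2 (x-b1)+ + c3 (x-b2)+);
    end segments extrapolate.
    """

    breakpoints: np.ndarray  # (2,)
    coef: np.ndarray  # (4,) intercept, slope, hinge1, hinge2
    single_segment: bool = False

    def predict(self, area) -> np.ndarray | float:
        x = np.asarray(area, dtype=float)
        y = (
            self.coef[0]
            + self.coef[1] * x
            + self.coef[2] * np.maximum(x - self.breakpoints[0], 0.0)
            + self.coef[3] * np.maximum(x - self.breakpoints[1], 0.0)
        )
        return float(y) if np.ndim(area) == 0 else y


def _hinge_lstsq(x: np.ndarray, y: np.ndarray, b1: float, b2: float):
    basis = np.column_stack(
        [np.ones_like(x), x, np.maximum(x - b1, 0.0), np.maximum(x - b2, 0.0)]
    )
    coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
    sse = float(np.sum((basis @ coef - y) ** 2))
    return coef, sse


def fit_rfp_size_model(
    cells: list[tuple[float, float]] | np.ndarray,
    min_cells: int = 100,
) -> RfpSizeModel:
    """Fit the 3-segment piecewise-linear mean-RFP-vs-area model.

    Candidate interior breakpoints are scanned over area quantiles, the
    best pair refined by Nelder-Mead on the least-squares objective.  With
    insufficient spread in areas a single straight line is fitted and the
    model flagged ``single_segment``.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (area, mean_rfp) pairs")
    if len(arr) < min_cells:
        raise ValueError(f"need >= {min_cells} cells, got {len(arr)}")
    x, y = arr[:, 0], arr[:, 1]
    qs = np.quantile(x, np.linspace(0.1, 0.9, 17))
    if np.ptp(qs) <= 1e-9:
        coef = np.zeros(4)
        coef[:2] = np.polyfit(x, y, 1)[::-1] if np.ptp(x) > 0 else (y.mean(), 0.0)
        warnings.warn("insufficient area spread; single-segment RFP model")
        return RfpSizeModel(
            breakpoints=np.array([x.min(), x.max()]), coef=coef,
            single_segment=True,
        )
    best = None
    for i, b1 in enumerate(qs):
        for b2 in qs[i + 2:]:
            coef, sse = _hinge_lstsq(x, y, b1, b2)
            if best is None or sse < best[0]:
                best = (sse, b1, b2, coef)
    _, b1, b2, _ = best

    lo, hi = x.min(), x.max()

    def objective(b):
        bb1, bb2 = sorted(b)
        if bb1 <= lo or bb2 >= hi or bb2 - bb1 < 1e-6 * (hi - lo):
            return np.inf
        return _hinge_lstsq(x, y, bb1, bb2)[1]

    res = minimize(objective, x0=[b1, b2], method="Nelder-Mead",
                   options={"xatol": 1e-3 * (hi - lo), "fatol": 1e-9})
    if np.isfinite(res.fun):
        b1, b2 = sorted(res.x)
    coef, _ = _hinge_lstsq(x, y, b1, b2)
    return RfpSizeModel(breakpoints=np.array([b1, b2]), coef=coef)


def intensity_ratio(
    pixels: np.ndarray,
    gfp: np.ndarray,
    rfp: np.ndarray,
    model: RfpSizeModel,
) -> float:
    """Size-normalized total GFP / total RFP intensity ratio.

    The ratio of channel totals is rescaled by the fold difference of the
    observed mean RFP to its size expectation, which reduces to
    sum(GFP) / (N * m(N)): the observed RFP total cancels, but a zero RFP
    total still signals a ruptured cell and raises.
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=int))
    n = len(pixels)
    if n == 0:
        raise ValueError("empty cell")
    g = float(gfp[pixels[:, 0], pixels[:, 1]].sum())
    r = float(rfp[pixels[:, 0], pixels[:, 1]].sum())
    if r <= 0:
        raise RupturedCellError("zero RFP total inside the cell")
    expected = model.predict(float(n))
    if expected <= 0:
        raise ValueError("non-positive expected RFP at this cell size")
    return g / (n * expected)


@dataclass
class FeatureVector:
    """Intensity ratio plus the five morphological log-ratio distances.

    ``d_neck`` is None for lone cells (no neck landmark); distances are
    None with ``missing_reason`` set when the GFP channel is empty.
    """

    intensity_ratio: float | None = None
    d_between_proteins: float | None = None
    d_mass_center: float | None = None
    d_cell_center: float | None = None
    d_periphery: float | None = None
    d_neck: float | None = None
    missing_reason: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) if getattr(self, name) is not None else np.nan
             for name in FEATURE_NAMES],
            dtype=float,
        )


def _channel_distribution(values: np.ndarray) -> np.ndarray | None:
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    total = v.sum()
    if total <= 0:
        return None
    return v / total


def morphological_distances(
    pixels: np.ndarray,
    gfp: np.ndarray,
    rfp: np.ndarray,
    edge_map: EdgeDistanceMap,
    neck_position: np.ndarray | None = None,
    max_pairwise: int = 4000,
) -> dict[str, float | None]:
    """The five morphological log-ratio distances for one cell.

    Negative (background-subtracted) intensities are clipped to 0 before
    normalisation.  The between-proteins numerator is the GFP-GFP expected
    pairwise distance and its denominator the GFP-RFP cross expectation
    ("expected distance between a protein and a RFP marker"); the four
    landmark distances divide the GFP expectation by the RFP expectation of
    the same functional.  Pairwise expectations are exact double sums
    (chunked above ``max_pairwise`` pixels to bound memory).
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=int))
    coords = pixels.astype(float)
    p_g = _channel_distribution(gfp[pixels[:, 0], pixels[:, 1]])
    p_r = _channel_distribution(rfp[pixels[:, 0], pixels[:, 1]])
    out: dict[str, float | None] = {name: None for name in DISTANCE_NAMES}
    if p_g is None:
        out["missing_reason"] = "all-zero GFP in cell"
        return out
    if p_r is None:
        out["missing_reason"] = "all-zero RFP in cell"
        return out

    center = coords.mean(axis=0)
    edge_d = edge_map.dist[pixels[:, 0], pixels[:, 1]]

    # a point mass sitting exactly on a landmark would give a zero
    # expectation; distances are floored at half a pixel (the raster
    # resolution) so the log ratio stays finite
    floor = 0.5

    def landmark_ratio(point_or_values, name: str) -> float:
        if isinstance(point_or_values, str) and point_or_values == "edge":
            dg = float(p_g @ edge_d)
            dr = float(p_r @ edge_d)
        else:
            d = np.linalg.norm(coords - point_or_values, axis=1)
            dg = float(p_g @ d)
            dr = float(p_r @ d)
        if dg == dr:
            return 0.0
        return float(np.log(max(dg, floor) / max(dr, floor)))

    out["d_cell_center"] = landmark_ratio(center, "d_cell_center")
    mass_g = p_g @ coords
    mass_r = p_r @ coords
    d_g = float(p_g @ np.linalg.norm(coords - mass_g, axis=1))
    d_r = float(p_r @ np.linalg.norm(coords - mass_r, axis=1))
    out["d_mass_center"] = (
        0.0 if d_g == d_r
        else float(np.log(max(d_g, floor) / max(d_r, floor)))
    )
    out["d_periphery"] = landmark_ratio("edge", "d_periphery")
    if neck_position is not None:
        out["d_neck"] = landmark_ratio(np.asarray(neck_position, float), "d_neck")

    n = len(coords)
    if n <= max_pairwise:
        dmat = cdist(coords, coords)
        e_gg = float(p_g @ dmat @ p_g)
        e_gr = float(p_g @ dmat @ p_r)
    else:
        e_gg = e_gr = 0.0
        for start in range(0, n, max_pairwise):
            block = cdist(coords[start:start + max_pairwise], coords)
            e_gg += float(p_g[start:start + max_pairwise] @ block @ p_g)
            e_gr += float(p_g[start:start + max_pairwise] @ block @ p_r)
    out["d_between_proteins"] = (
        float(np.log(e_gg / e_gr)) if e_gg > 0 and e_gr > 0 else 0.0
    )
    return out
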