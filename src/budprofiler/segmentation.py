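"""Foreground/background segmentation of the RFP channel.

The whole-cell RFP marker separates cells from background, but its level
varies from cell to cell and vacuoles can be dimmer than inter-cell gaps, so
no global intensity threshold works.  Instead the image is modelled as a
two-state (background / foreground) hidden Markov chain with Normal
emissions, run once over rows and once over columns ("pseudo-2D"), and the
two per-pixel posteriors are averaged.

The module also provides the mean-image background correction and the
expected edge-distance map used by contour extraction, the shape quality
measures and the distance-to-periphery feature.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Micrograph",
    "SegmentationResult",
    "EdgeDistanceMap",
    "BackgroundModel",
    "DegenerateImageError",
    "MOVES",
    "compute_background_image",
    "correct_image",
    "segment_foreground",
    "edge_distance_map",
    "transition_power",
]

#: move set for the edge-distance map: axial, diagonal and knight moves,
#: with their geometric step lengths.
MOVES: tuple[tuple[int, int, float], ...] = tuple(
    [(dr, dc, 1.0) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
    + [(dr, dc, np.sqrt(2.0)) for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1))]
    + [
        (dr, dc, np.sqrt(5.0))
        for dr, dc in (
            (-2, -1), (-2, 1), (2, -1), (2, 1),
            (-1, -2), (-1, 2), (1, -2), (1, 2),
        )
    ]
)


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity variation to segment."""


@dataclass
class Micrograph:
    """A paired two-channel micrograph (RFP marker + GFP tag).

    Intensities are stored as floats in corrected camera units; both
    channels must share one pixel grid.
    """

    rfp: np.ndarray
    gfp: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.rfp = np.asarray(self.rfp, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.rfp.shape != self.gfp.shape:
            raise ValueError(
                f"channel shapes differ: rfp {self.rfp.shape} vs gfp {self.gfp.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.rfp.shape


@dataclass
class BackgroundModel:
    """Pixel-wise mean background with a defective-CCD-pixel mask."""

    background: np.ndarray
    defective: np.ndarray  # boolean mask of zero-variance pixels


@dataclass
class SegmentationResult:
    """Per-pixel foreground posterior with the fitted HMM parameters.

    ``means``/``sds`` are ordered (background, foreground); ``transmat`` is
    row-stochastic in the same state order.  The foreground state is, by
    convention, the higher-mean state.
    """

    foreground_prob: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    converged: bool = True

    @property
    def background_prob(self) -> np.ndarray:
        return 1.0 - self.foreground_prob


@dataclass
class EdgeDistanceMap:
    """Expected geometric distance to background for every pixel.

    Background-certain pixels carry 0.  ``dist`` is in pixel units.
    """

    dist: np.ndarray
    moves: tuple[tuple[int, int, float], ...] = field(default=MOVES)


def compute_background_image(images, method: str = "mean") -> BackgroundModel:
    """Combine a collection of RFP images into a background image.

    ``method='mean'`` is the pixel-wise average, appropriate when the
    collection is large enough that cells occupy any given pixel in only a
    small fraction of images.  ``method='median'`` is a robust variant for
    small collections, where the mean would still carry an appreciable
    share of cell signal; ``'scalar'`` reduces the estimate to the global
    median level (for collections too small for even the median to be
    background-dominated).

    Defective CCD pixels systematically report the same value in every
    image; they are flagged as the pixels with zero variance across the
    collection (only meaningful for >= 2 images).
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    ref_shape = np.asarray(images[0]).shape
    for i, img in enumerate(images):
        if np.asarray(img).shape != ref_shape:
            raise ValueError(
                f"image {i} has shape {np.asarray(img).shape}, expected {ref_shape}"
            )
    stack = np.stack([np.asarray(img, dtype=float) for img in images])
    if method == "mean":
        background = stack.mean(axis=0)
    elif method == "median":
        background = np.median(stack, axis=0)
    elif method == "scalar":
        background = np.full(ref_shape, np.median(stack))
    else:
        raise ValueError(f"unknown background method {method!r}")
    if len(images) >= 2:
        defective = stack.var(axis=0) == 0.0
    else:
        defective = np.zeros(ref_shape, dtype=bool)
    return BackgroundModel(background=background, defective=defective)


def correct_image(image: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Subtract the background image, flooring at 0."""
    out = np.asarray(image, dtype=float) - model.background
    np.clip(out, 0.0, None, out=out)
    return out


def _fit_1d_hmm(values: np.ndarray, lengths, tol: float, n_iter: int):
    """Fit a 2-state Gaussian HMM on a batch of independent 1-D sequences.

    Initialisation follows a 2-quantile split (below/above the median) for
    the emissions and 0.95 self-transition.  Returns per-sample foreground
    posteriors plus (means, sds, transmat) with state order (bg, fg).
    """
    from hmmlearn.hmm import GaussianHMM

    x = values.reshape(-1, 1)
    med = np.median(x)
    lo, hi = x[x[:, 0] <= med], x[x[:, 0] > med]
    if hi.size == 0:  # constant-majority image; split around the mean instead
        lo, hi = x[x[:, 0] <= x.mean()], x[x[:, 0] > x.mean()]
    if hi.size == 0:
        raise DegenerateImageError("image is constant; nothing to segment")
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        init_params="",
        params="stmc",
        tol=tol,
        n_iter=n_iter,
    )
    model.startprob_ = np.array([lo.size, hi.size], dtype=float) / x.size
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = np.array([[lo.mean()], [hi.mean()]])
    var_floor = max(1e-6, 1e-6 * float(x.var()))
    model.covars_ = np.maximum(
        np.array([[lo.var()], [hi.var()]]), var_floor
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, lengths=lengths)
        post = model.predict_proba(x, lengths=lengths)
    means = model.means_[:, 0].copy()
    sds = np.sqrt(np.array(model.covars_).reshape(2))
    transmat = model.transmat_.copy()
    order = np.argsort(means)  # background = lower mean
    post = post[:, order]
    return (
        post[:, 1],
        means[order],
        sds[order],
        transmat[np.ix_(order, order)],
        bool(model.monitor_.converged),
    )


def segment_foreground(
    rfp: np.ndarray, tol: float = 1e-6, n_iter: int = 200
) -> SegmentationResult:
    """Segment an RFP image with the pseudo-2D hidden Markov model.

    EM is run under the assumption that rows are independent chains, then
    again treating columns as independent chains; the returned foreground
    probability is the average of the two posteriors.  Reported emission and
    transition parameters are the average of the two (state-aligned) fits.
    """
    rfp = np.asarray(rfp, dtype=float)
    if rfp.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(rfp) == 0:
        raise DegenerateImageError("image is constant; nothing to segment")
    h, w = rfp.shape
    p_row, m1, s1, t1, c1 = _fit_1d_hmm(rfp.ravel(), [w] * h, tol, n_iter)
    p_col, m2, s2, t2, c2 = _fit_1d_hmm(rfp.T.ravel(), [h] * w, tol, n_iter)
    fg = 0.5 * (p_row.reshape(h, w) + p_col.reshape(w, h).T)
    converged = c1 and c2
    if not converged:
        warnings.warn("EM did not converge within the iteration cap; "
                      "returning the best estimate", RuntimeWarning)
    return SegmentationResult(
        foreground_prob=fg,
        means=0.5 * (m1 + m2),
        sds=0.5 * (s1 + s2),
        transmat=0.5 * (t1 + t2),
        converged=converged,
    )


def transition_power(transmat: np.ndarray, s: float) -> np.ndarray:
    """Raise a 2x2 row-stochastic matrix to a (possibly fractional) power.

    Closed form through the eigendecomposition: the second eigenvalue is
    lam = 1 - a - b for T = [[1-a, a], [b, 1-b]]; a negative lam has no real
    fractional power and is clamped to 0.
    """
    a = transmat[0, 1]
    b = transmat[1, 0]
    if a + b == 0:
        return np.eye(2)
    lam = max(1.0 - a - b, 0.0)
    ls = lam**s
    return (
        np.array([[b, a], [b, a]]) + ls * np.array([[a, -a], [-b, b]])
    ) / (a + b)


def edge_distance_map(
    seg: SegmentationResult,
    bg_certain: float = 0.5,
    border_background: bool = True,
) -> EdgeDistanceMap:
    """Expected distance to background for every pixel.

    Pixels whose background probability is >= ``bg_certain`` are treated as
    background and carry distance 0.  From a foreground pixel the map
    satisfies

        d(x) = min over moves y->x of  s + (1 - b(y, s)) * d(y)

    where s in {1, sqrt 2, sqrt 5} is the geometric step length and
    b(y, s) is the probability that the walk is absorbed by background at
    y: either y itself is background (its posterior q), or the HMM state
    chain switched to background over the step — the transition matrix
    raised to the step length gives that prior, and the two routes combine
    as independent events,

        b = 1 - (1 - q(y)) * (1 - p_s),   p_s = (T^s)[fg, bg].

    Dim inter-cell valleys (intermediate q) thereby shorten expected
    distances around them even when they are not classified background,
    which is what lets clump-internal structure surface in the contour.

    In the deterministic limit (posteriors in {0, 1}, transitions ->
    identity) b vanishes and the map is exactly the shortest-path distance
    under the axial/diagonal/knight move set.  Image borders are treated as
    certain background (cells touching the frame are low-confidence anyway).

    The fixed point is computed with a label-correcting heap sweep, linear
    in pixels times the constant move set for the images at hand.
    """
    q = np.clip(seg.background_prob, 0.0, 1.0)
    h, w = q.shape
    bg = q >= bg_certain
    if border_background and h > 2 and w > 2:
        bg = bg.copy()
        bg[0, :] = bg[-1, :] = True
        bg[:, 0] = bg[:, -1] = True
    if not bg.any():
        bg = np.zeros_like(bg)
        bg[0, :] = bg[-1, :] = True
        bg[:, 0] = bg[:, -1] = True

    # pre-compute the absorption probability per move length
    step_lengths = sorted({s for _, _, s in MOVES})
    p_s = {s: transition_power(seg.transmat, s)[1, 0] for s in step_lengths}

    def absorb(qv: float, s: float) -> float:
        return 1.0 - (1.0 - qv) * (1.0 - p_s[s])

    dist = np.full((h, w), np.inf)
    dist[bg] = 0.0
    heap: list[tuple[float, int, int]] = [
        (0.0, r, c) for r, c in zip(*np.nonzero(bg))
    ]
    heapq.heapify(heap)
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, s in MOVES:
            rr, cc = r + dr, c + dc
            if rr < 0 or rr >= h or cc < 0 or cc >= w or bg[rr, cc]:
                continue
            cand = s + (1.0 - absorb(q[r, c], s)) * d
            if cand < dist[rr, cc] - 1e-15:
                dist[rr, cc] = cand
                heapq.heappush(heap, (cand, rr, cc))
    return EdgeDistanceMap(dist=dist)
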