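"""Probabilistic cell confidence for identified shapes.

Rather than characterising every artifact class, each identified object is
scored with four quality measures — a density measure from the closed-form
moment-ellipse fit, a perimeter-consistency measure against the Ramanujan
ellipse-perimeter approximation, the log coefficient of variation of
(centre distance + edge distance) which vanishes for a perfect disc, and
the mean RFP level — and the population of objects is modelled as a
two-component mixture: a size-interpolated diagonal Normal for true cells
versus a uniform alternative spanning the observed extremes.  The posterior
under this mixture is the cell probability used as a weight downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ellipse import ramanujan_perimeter  # noqa: F401  (re-exported here)
from .segmentation import EdgeDistanceMap

__all__ = [
    "MomentFit",
    "QualityVector",
    "ConfidenceModel",
    "ShapeTooSmallError",
    "moment_ellipse_fit",
    "ramanujan_perimeter",
    "quality_vector",
    "perimeter_pixel_count",
    "is_artifact",
    "fit_confidence_model",
    "cell_posterior",
    "estimate_mixing",
    "pair_probability",
    "lone_weight",
    "N_BINS",
    "QUALITY_NAMES",
]

N_BINS = 7
QUALITY_NAMES = ("q_density", "q_perimeter", "q_circular", "mean_rfp")

#: pre-filter defaults for obvious artifacts (unprinted in the original
#: protocol; exposed as configuration)
MIN_AREA = 50
MIN_AXIS = 3.0
CV_FLOOR = 1e-3


class ShapeTooSmallError(ValueError):
    """Shape has too few pixels for a moment fit (< 5)."""


@dataclass
class MomentFit:
    """Closed-form best-fit ellipse of an arbitrary pixel shape.

    A uniform-density ellipse matching the shape's first and second moments
    has its centre at the shape centroid and semi-axes equal to twice the
    square roots of the second-central-moment eigenvalues.  ``density`` is
    pixel count / fitted ellipse area; discrete shapes have density < 1
    except for the tiniest objects, so density >= 1 marks an artifact.
    """

    n: int
    centroid: np.ndarray
    second_moments: np.ndarray  # 2x2 central moment matrix
    major: float  # semi-axis, px
    minor: float
    density: float


@dataclass
class QualityVector:
    """The four per-object quality measures (finite after flooring)."""

    q_density: float
    q_perimeter: float
    q_circular: float
    mean_rfp: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.q_density, self.q_perimeter, self.q_circular, self.mean_rfp]
        )


def moment_ellipse_fit(pixels: np.ndarray) -> MomentFit:
    """Fit an ellipse to a pixel shape by matching moments (closed form)."""
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    n = len(pixels)
    if n < 5:
        raise ShapeTooSmallError(f"{n} pixels; need >= 5 for a moment fit")
    centroid = pixels.mean(axis=0)
    d = pixels - centroid
    m2 = d.T @ d / n
    evals = np.linalg.eigvalsh(m2)  # ascending
    evals = np.maximum(evals, 1e-12)
    minor, major = 2.0 * np.sqrt(evals)
    density = n / (np.pi * major * minor)
    return MomentFit(
        n=n, centroid=centroid, second_moments=m2,
        major=float(major), minor=float(minor), density=float(density),
    )


def is_artifact(
    fit: MomentFit, min_area: int = MIN_AREA, min_axis: float = MIN_AXIS
) -> bool:
    """Pre-filter: tiny, needle-thin or over-dense objects are artifacts."""
    return fit.n < min_area or fit.minor < min_axis or fit.density >= 1.0


def perimeter_pixel_count(pixels: np.ndarray) -> int:
    """Shape pixels with 3 or more non-shape pixels among their 8 neighbours."""
    pixels = np.atleast_2d(np.asarray(pixels, dtype=int))
    off = pixels.min(axis=0) - 1
    local = pixels - off
    mask = np.zeros(local.max(axis=0) + 2, dtype=bool)
    mask[local[:, 0], local[:, 1]] = True
    outside = np.zeros(mask.shape, dtype=int)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.zeros_like(mask)
            src = mask[
                max(-dr, 0):mask.shape[0] - max(dr, 0),
                max(-dc, 0):mask.shape[1] - max(dc, 0),
            ]
            shifted[
                max(dr, 0):mask.shape[0] - max(-dr, 0),
                max(dc, 0):mask.shape[1] - max(-dc, 0),
            ] = src
            outside += (~shifted).astype(int)
    return int(np.count_nonzero(mask & (outside >= 3)))


def quality_vector(
    pixels: np.ndarray,
    fit: MomentFit,
    edge_map: EdgeDistanceMap,
    rfp: np.ndarray,
    cv_floor: float = CV_FLOOR,
) -> QualityVector:
    """The four quality measures for one shape.

    q_density   = log(1 - density)                (density < 1 enforced)
    q_perimeter = log(perimeter pixels / Ramanujan perimeter of the fit)
    q_circular  = log CV of (distance to centroid + edge distance);
                  exactly-circular shapes have zero variance because the
                  two distances sum to the radius, hence the CV floor.
    mean_rfp    = mean marker intensity over the shape.
    """
    if fit.density >= 1.0:
        raise ValueError("density >= 1 objects are artifacts; no quality vector")
    pixels = np.atleast_2d(np.asarray(pixels, dtype=int))
    q_d = float(np.log(1.0 - fit.density))
    perim = perimeter_pixel_count(pixels)
    q_p = float(np.log(max(perim, 1) / ramanujan_perimeter(fit.major, fit.minor)))
    center_d = np.linalg.norm(pixels - fit.centroid, axis=1)
    edge_d = edge_map.dist[pixels[:, 0], pixels[:, 1]]
    s = center_d + edge_d
    mean_s = float(s.mean())
    cv = float(s.std() / mean_s) if mean_s > 0 else 0.0
    q_c = float(np.log(max(cv, cv_floor)))
    mean_rfp = float(rfp[pixels[:, 0], pixels[:, 1]].mean())
    return QualityVector(q_d, q_p, q_c, mean_rfp)


@dataclass
class ConfidenceModel:
    """Size-binned Normal cell model against a uniform artifact alternative.

    The four quality measures are modelled per size bin by independent
    Normals (7 bins across the training-size range, anchors at equal
    quantiles); between anchors the quality vector is treated as a linear
    interpolation of the two bin variables, so the mean interpolates
    linearly and the variance as (1-t)^2 s_k^2 + t^2 s_{k+1}^2.  The
    alternative is uniform over the extremes observed in the full object
    collection.  ``rho`` is the mixing weight of the cell component.
    """

    anchors: np.ndarray  # (N_BINS,) increasing size anchors
    means: np.ndarray  # (N_BINS, 4)
    sds: np.ndarray  # (N_BINS, 4)
    support_lo: np.ndarray  # (4,)
    support_hi: np.ndarray  # (4,)
    rho: float = 0.5
    borrowed_bins: tuple = ()

    def interpolate(self, size: float) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) of the 4 measures at a given cell size."""
        size = float(np.clip(size, self.anchors[0], self.anchors[-1]))
        k = int(np.searchsorted(self.anchors, size, side="right") - 1)
        k = min(max(k, 0), len(self.anchors) - 2)
        span = self.anchors[k + 1] - self.anchors[k]
        t = 0.0 if span == 0 else (size - self.anchors[k]) / span
        mean = (1.0 - t) * self.means[k] + t * self.means[k + 1]
        var = (1.0 - t) ** 2 * self.sds[k] ** 2 + t**2 * self.sds[k + 1] ** 2
        return mean, np.sqrt(var)

    def log_uniform_density(self) -> float:
        return float(-np.sum(np.log(self.support_hi - self.support_lo)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "anchors": self.anchors.tolist(),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "support_lo": self.support_lo.tolist(),
                "support_hi": self.support_hi.tolist(),
                "rho": self.rho,
                "borrowed_bins": list(self.borrowed_bins),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceModel":
        d = json.loads(text)
        return cls(
            anchors=np.array(d["anchors"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            support_lo=np.array(d["support_lo"]),
            support_hi=np.array(d["support_hi"]),
            rho=float(d["rho"]),
            borrowed_bins=tuple(d["borrowed_bins"]),
        )


def fit_confidence_model(
    training: list[tuple[QualityVector, float]],
    all_objects: list[tuple[QualityVector, float]] | None = None,
    n_bins: int = N_BINS,
    sd_floor_fraction: float = 1e-3,
) -> ConfidenceModel:
    """Fit the size-binned Normal cell model from labelled cells.

    ``training`` holds (quality vector, size) for objects known to be
    cells; ``all_objects`` (default: the training set) supplies the
    extremes that define the uniform alternative.  An empty bin borrows the
    nearest populated bin's parameters and is flagged.
    """
    if len(training) < 20:
        raise ValueError("need >= 20 labelled training cells")
    q = np.array([t[0].as_array() for t in training])
    sizes = np.array([t[1] for t in training], dtype=float)
    anchors = np.quantile(sizes, (np.arange(n_bins) + 0.5) / n_bins)
    anchors = np.maximum.accumulate(anchors)
    if anchors[0] == anchors[-1]:
        raise ValueError("training sizes must span >= 2 bins")
    edges = np.quantile(sizes, np.arange(1, n_bins) / n_bins)
    bin_of = np.searchsorted(edges, sizes, side="right")
    full = all_objects if all_objects is not None else training
    qa = np.array([t[0].as_array() for t in full])
    lo, hi = qa.min(axis=0), qa.max(axis=0)
    pad = np.maximum(1e-6, 1e-6 * (hi - lo))
    lo, hi = lo - pad, hi + pad
    sd_floor = sd_floor_fraction * np.maximum(hi - lo, 1e-6)
    means = np.zeros((n_bins, 4))
    sds = np.zeros((n_bins, 4))
    populated = []
    for k in range(n_bins):
        sel = bin_of == k
        if sel.sum() >= 2:
            means[k] = q[sel].mean(axis=0)
            sds[k] = np.maximum(q[sel].std(axis=0, ddof=1), sd_floor)
            populated.append(k)
    borrowed = []
    for k in range(n_bins):
        if k not in populated:
            nearest = min(populated, key=lambda j: abs(j - k))
            means[k] = means[nearest]
            sds[k] = sds[nearest]
            borrowed.append(k)
    return ConfidenceModel(
        anchors=anchors, means=means, sds=sds,
        support_lo=lo, support_hi=hi, borrowed_bins=tuple(borrowed),
    )


def _log_normal_pdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> float:
    z = (x - mean) / sd
    return float(np.sum(-0.5 * z**2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)))


def cell_posterior(
    q: QualityVector, size: float, model: ConfidenceModel,
    rho: float | None = None,
) -> float:
    """Posterior probability that an object is a cell (Bayes, 2 components).

    Quality values outside the uniform support use the support-edge density
    for the alternative component (the cell Normal still applies).
    """
    rho = model.rho if rho is None else rho
    mean, sd = model.interpolate(size)
    log_cell = _log_normal_pdf(q.as_array(), mean, sd)
    log_alt = model.log_uniform_density()
    a = np.log(rho) + log_cell
    b = np.log1p(-rho) + log_alt
    m = max(a, b)
    return float(np.exp(a - m) / (np.exp(a - m) + np.exp(b - m)))


def estimate_mixing(
    objects: list[tuple[QualityVector, float]],
    model: ConfidenceModel,
    rho0: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> float:
    """Soft-EM for the mixing parameter rho, all other parameters fixed.

    The update is rho <- mean posterior over the collection; converged when
    |delta rho| < tol.
    """
    if not objects:
        raise ValueError("empty object collection")
    rho = rho0
    for _ in range(max_iter):
        post = np.array(
            [cell_posterior(q, size, model, rho=rho) for q, size in objects]
        )
        new = float(post.mean())
        if abs(new - rho) < tol:
            return new
        rho = new
    return rho


def pair_probability(mother_p: float, bud_p: float) -> float:
    """Probability that a mother-bud pair is a correctly identified pair."""
    return float(mother_p * bud_p)


def lone_weight(cell_p: float, partner_p: float) -> float:
    """Weight with which a paired cell is partially a lone cell.

    If the putative partner is an artifact (probability 1 - partner_p), the
    cell itself is still a cell with probability cell_p.
    """
    return float(cell_p * (1.0 - partner_p))
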