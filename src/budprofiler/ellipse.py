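"""Robust multi-ellipse regression on clump contours.

Cells appear singly or in clumps; the number of cells in a clump is found
by repeatedly fitting ellipses to the clump's contour pixels with a robust
(Cauchy) loss, harvesting the best local minimum, consuming the contour
pixels it explains and repeating until nothing more can be consumed.

An ellipse is the zero set of the algebraic error

    e(p) = (p - c)^T A (p - c) - r^2

with A = R(theta) diag(exp(-g), exp(g)) R(theta)^T and
g = -log(ratio_min) * eps^2 / (1 + eps^2).  det A = 1, so r is the
geometric-mean radius; eps = 0 reduces A to the identity and e to the
circle form |p - c|^2 - r^2, and the minor/major axis ratio exp(-g) is
bounded below by ``ratio_min`` for every parameter value, which excludes
hyperbolae and degenerate conics by construction.

Coordinates are 0-based (row, col) pixel centres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import EdgeDistanceMap

__all__ = [
    "EllipseParams",
    "ContourSet",
    "algebraic_error",
    "normalized_error",
    "extract_contour_pixels",
    "fit_ellipses_robust",
    "robust_objective",
    "DEFAULT_RATIO_MIN",
]

DEFAULT_RATIO_MIN = 0.5  # lower bound on minor/major axis ratio
CONTOUR_THICKNESS = 5.0  # px; also the expected error sigma of the robust loss


@dataclass
class EllipseParams:
    """Parametric ellipse: centre, scale, eccentricity and orientation.

    ``r`` is proportional to the circle radius at ``eps`` = 0 (it is the
    geometric-mean radius in general); ``theta`` is the major-axis angle in
    radians, reduced to [0, pi).
    """

    cy: float  # centre row
    cx: float  # centre col
    r: float
    eps: float = 0.0
    theta: float = 0.0
    ratio_min: float = DEFAULT_RATIO_MIN

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("ellipse scale r must be positive")
        if self.eps < 0:
            raise ValueError("eccentricity parameter must be >= 0")
        self.theta = float(np.mod(self.theta, np.pi))

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cy, self.cx])

    @property
    def _g(self) -> float:
        return -np.log(self.ratio_min) * self.eps**2 / (1.0 + self.eps**2)

    @property
    def matrix(self) -> np.ndarray:
        """The constrained quadratic-form matrix A (det A = 1)."""
        g = self._g
        ct, st = np.cos(self.theta), np.sin(self.theta)
        rot = np.array([[ct, -st], [st, ct]])
        return rot @ np.diag([np.exp(-g), np.exp(g)]) @ rot.T

    @property
    def semi_axes(self) -> tuple[float, float]:
        """(major, minor) semi-axis lengths in pixels."""
        g = self._g
        return self.r * np.exp(g / 2.0), self.r * np.exp(-g / 2.0)

    @property
    def area(self) -> float:
        a, b = self.semi_axes
        return np.pi * a * b

    def boundary_points(self, n: int = 100) -> np.ndarray:
        """Sample n points exactly on the ellipse, as (row, col) pairs.

        The major axis direction in (row, col) space is
        (cos theta, sin theta).
        """
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        ct, st = np.cos(self.theta), np.sin(self.theta)
        dy = a * np.cos(t) * ct - b * np.sin(t) * st
        dx = a * np.cos(t) * st + b * np.sin(t) * ct
        return np.column_stack([self.cy + dy, self.cx + dx])

    def contains(self, points: np.ndarray) -> np.ndarray:
        return algebraic_error(self, points) <= 0.0


def algebraic_error(e: EllipseParams, points: np.ndarray) -> np.ndarray:
    """Algebraic error (p-c)^T A (p-c) - r^2; 0 exactly on the ellipse.

    Negative inside, positive outside.  ``points`` is (..., 2) in
    (row, col); a single pair is accepted and returns a scalar.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    g = e._g
    ct, st = np.cos(e.theta), np.sin(e.theta)
    dy = pts[:, 0] - e.cy
    dx = pts[:, 1] - e.cx
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    out = np.exp(-g) * u**2 + np.exp(g) * v**2 - e.r**2
    return float(out[0]) if np.ndim(points) == 1 else out


def normalized_error(e: EllipseParams, points: np.ndarray) -> np.ndarray:
    """Algebraic error scaled to approximate geometric pixel distance.

    Near the boundary |p-c|^2 - r^2 = (|p-c| - r)(|p-c| + r) ~= 2 r d, so
    dividing by 2 r puts the residual on the pixel scale where the robust
    expected error (5 px, the contour thickness) applies.
    """
    return algebraic_error(e, points) / (2.0 * e.r)


@dataclass
class ContourSet:
    """Contour pixels of one foreground clump, with consumption flags."""

    pixels: np.ndarray  # (n, 2) int (row, col)
    clump_id: int = 0
    removed: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels))
        if self.removed is None:
            self.removed = np.zeros(len(self.pixels), dtype=bool)

    @property
    def active(self) -> np.ndarray:
        return self.pixels[~self.removed]

    def __len__(self) -> int:
        return len(self.pixels)


def extract_contour_pixels(
    edge_map: EdgeDistanceMap, thickness: float = CONTOUR_THICKNESS
) -> list[ContourSet]:
    """Contour pixels: foreground pixels within ``thickness`` of background.

    Foreground pixels are those with positive edge distance; the clumps are
    the 8-connected components of the foreground, each yielding one
    ContourSet (empty foreground yields an empty list).
    """
    dist = edge_map.dist
    fg = dist > 0
    if not fg.any():
        return []
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    contour = fg & (dist <= thickness)
    out = []
    for cid in range(1, n + 1):
        pix = np.argwhere(contour & (labels == cid))
        if len(pix):
            out.append(ContourSet(pixels=pix, clump_id=cid))
    return out


def _tukey_rho(res: np.ndarray, sigma: float) -> np.ndarray:
    z2 = np.minimum((res / sigma) ** 2, 1.0)
    return sigma**2 / 6.0 * (1.0 - (1.0 - z2) ** 3)


def _tukey_weight(res: np.ndarray, sigma: float) -> np.ndarray:
    z2 = (res / sigma) ** 2
    w = np.where(z2 < 1.0, (1.0 - np.minimum(z2, 1.0)) ** 2, 0.0)
    return np.maximum(w, 1e-9)  # tiny floor keeps the IRLS system regular


def robust_objective(
    e: EllipseParams, points: np.ndarray, sigma: float = CONTOUR_THICKNESS
) -> float:
    """Redescending (Tukey biweight) objective with scale ``sigma``.

    The per-point loss saturates at sigma^2/6 beyond ``sigma`` pixels, so
    contour pixels belonging to *other* ellipses contribute a constant and
    exert no pull: a candidate matching one circle of a clump precisely
    beats a sloppy ellipse enclosing the whole clump, which is what makes
    the iterative multi-ellipse harvest work.  The IRLS weight is the
    biweight (1 - (e/sigma)^2)^2 inside the scale and 0 outside.
    """
    res = normalized_error(e, points)
    return float(np.sum(_tukey_rho(res, sigma)))


def _circumcircle(p: np.ndarray):
    """Centre and radius of the unique circle through 3 points (or None)."""
    (y1, x1), (y2, x2), (y3, x3) = p
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if abs(d) < 1e-9:
        return None
    s1, s2, s3 = x1**2 + y1**2, x2**2 + y2**2, x3**2 + y3**2
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = float(np.hypot(x1 - ux, y1 - uy))
    return (uy, ux), r


def _pack(e: EllipseParams) -> np.ndarray:
    return np.array([e.cy, e.cx, e.r, e.eps, e.theta])


def _unpack(v: np.ndarray, ratio_min: float) -> EllipseParams:
    return EllipseParams(
        cy=float(v[0]), cx=float(v[1]), r=max(float(v[2]), 0.5),
        eps=max(float(v[3]), 0.0), theta=float(v[4]), ratio_min=ratio_min,
    )


def _refine(
    init: EllipseParams,
    points: np.ndarray,
    sigma: float,
    max_iter: int = 40,
    xtol: float = 1e-3,
    ftol: float = 1e-9,
    trace: list | None = None,
) -> tuple[EllipseParams, float]:
    """Damped Gauss-Newton minimisation of the robust objective.

    Each step solves the IRLS normal equations with Levenberg damping and is
    accepted only if the true robust objective decreases, so the objective
    is non-increasing across iterations by construction.
    """
    v = _pack(init)
    ratio_min = init.ratio_min
    gmax = -np.log(ratio_min)
    fval = robust_objective(init, points, sigma)
    if trace is not None:
        trace.append(fval)
    lam = 1e-3

    def res_jac(vv: np.ndarray):
        cy, cx, r, eps, theta = vv
        r = max(r, 0.5)
        eps = max(eps, 0.0)
        g = gmax * eps**2 / (1.0 + eps**2)
        eg, emg = np.exp(g), np.exp(-g)
        ct, st = np.cos(theta), np.sin(theta)
        dy = points[:, 0] - cy
        dx = points[:, 1] - cx
        u = dy * ct + dx * st
        v_ = -dy * st + dx * ct
        quad = emg * u**2 + eg * v_**2
        res = (quad - r * r) / (2.0 * r)
        jac = np.empty((len(points), 5))
        jac[:, 0] = -(emg * u * ct - eg * v_ * st) / r  # d/d cy
        jac[:, 1] = -(emg * u * st + eg * v_ * ct) / r  # d/d cx
        jac[:, 2] = -1.0 - res / r
        dg_deps = gmax * 2.0 * eps / (1.0 + eps**2) ** 2
        jac[:, 3] = (-emg * u**2 + eg * v_**2) * dg_deps / (2.0 * r)
        jac[:, 4] = u * v_ * (emg - eg) / r
        return res, jac

    eye5 = np.eye(5)
    for _ in range(max_iter):
        res, jac = res_jac(v)
        w = _tukey_weight(res, sigma)
        jtw = jac.T * w
        g = jtw @ res
        hess = jtw @ jac
        step_ok = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(hess + lam * eye5, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = _unpack(v + delta, ratio_min)
            fcand = robust_objective(cand, points, sigma)
            if fcand <= fval:
                step_ok = True
                break
            lam *= 10.0
        if not step_ok:
            break
        converged = (
            np.max(np.abs(delta)) < xtol
            or fval - fcand < ftol * max(abs(fval), 1.0)
        )
        v = _pack(cand)
        fval = fcand
        if trace is not None:
            trace.append(fval)
        lam = max(lam / 10.0, 1e-8)
        if converged:
            break
    return _unpack(v, ratio_min), fval


def _inflate(e: EllipseParams, delta: float) -> EllipseParams:
    """Grow both semi-axes by ``delta`` pixels (band-bias correction).

    The contour band lies inside the cell, `thickness` pixels deep, so the
    least-squares ellipse tracks the band midline; pushing both axes out
    by half the thickness recovers the actual cell boundary.
    """
    a, b = e.semi_axes
    a2, b2 = a + delta, b + delta
    ratio = b2 / a2
    gmax = -np.log(e.ratio_min)
    g = min(-np.log(ratio), 0.999 * gmax)
    eps = float(np.sqrt(g / (gmax - g))) if g > 0 else 0.0
    return EllipseParams(
        cy=e.cy, cx=e.cx, r=float(np.sqrt(a2 * b2)), eps=eps,
        theta=e.theta, ratio_min=e.ratio_min,
    )


def _clamp_ok(e: EllipseParams, bbox, pad: float = 2.0) -> bool:
    """The ellipse must be bounded by the clamping rectangle of the contour."""
    (rmin, cmin), (rmax, cmax) = bbox
    pts = e.boundary_points(32)
    return bool(
        (pts[:, 0] >= rmin - pad).all()
        and (pts[:, 0] <= rmax + pad).all()
        and (pts[:, 1] >= cmin - pad).all()
        and (pts[:, 1] <= cmax + pad).all()
    )


def _center_background(e: EllipseParams, background_mask) -> bool:
    if background_mask is None:
        return False
    r = int(round(e.cy))
    c = int(round(e.cx))
    h, w = background_mask.shape
    if r < 0 or r >= h or c < 0 or c >= w:
        return True
    return bool(background_mask[r, c])


def fit_ellipses_robust(
    contour: ContourSet,
    seed: int | np.random.Generator = 0,
    background_mask: np.ndarray | None = None,
    sigma: float = CONTOUR_THICKNESS,
    mean_radius: float = 15.0,
    removal_sigma: float | None = None,
    min_width: float = 3.0,
    min_consumed_fraction: float = 0.10,
    candidates_per_ellipse: int = 10,
    ratio_min: float = DEFAULT_RATIO_MIN,
    min_support_pixels: int = 15,
    max_rounds: int = 30,
) -> list[EllipseParams]:
    """Iteratively fit ellipses to a clump contour with robust regression.

    Candidate budget is ~10x the number of expected ellipses, itself taken
    as (contour pixel count) / (2 pi mean_radius sigma).  Each candidate is
    seeded by the circumcircle of 3 random contour pixels (rejected if not
    bounded by the clamping rectangle or centred on background), given a
    small eccentricity (axis ratio 0.95) and a uniform random angle, then
    refined under the Cauchy loss.  The best ellipse consumes the contour
    pixels within ``removal_sigma`` (default: sigma) pixels of its
    boundary; an ellipse narrower than ``min_width`` px or consuming less
    than ``min_consumed_fraction`` of the pixel count expected from its
    perimeter and the contour thickness is rejected (its pixels are still
    consumed).  Iteration stops when no pixels can be removed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if removal_sigma is None:
        # |algebraic error| < sigma * r translates to sigma/2 geometric px
        removal_sigma = sigma / 2.0
    # eps giving minor/major ratio 0.95 under exp(-g(eps)) = 0.95
    g95 = -np.log(0.95)
    gmax = -np.log(ratio_min)
    eps0 = float(np.sqrt(g95 / (gmax - g95)))

    accepted: list[EllipseParams] = []
    for _round in range(max_rounds):
        pts = contour.active.astype(float)
        if len(pts) < max(3, min_support_pixels):
            break  # too few pixels to support even the smallest bud
        bbox = (pts.min(axis=0), pts.max(axis=0))
        n_expected = max(1.0, len(pts) / (2.0 * np.pi * mean_radius * sigma))
        n_cand = min(int(np.ceil(candidates_per_ellipse * n_expected)),
                     max(len(pts) // 3, 1))
        best: tuple[float, EllipseParams] | None = None
        for _ in range(n_cand):
            # localized 3-point sample: anchor uniformly, companions within
            # a random radius so small cells (buds) seed candidates too
            anchor = rng.integers(len(pts))
            scale = mean_radius * np.exp(rng.uniform(np.log(0.3), np.log(2.5)))
            near = np.nonzero(
                np.linalg.norm(pts - pts[anchor], axis=1) <= 2.0 * scale
            )[0]
            if len(near) < 3:
                continue
            idx = near[rng.choice(len(near), size=3, replace=False)]
            cc = _circumcircle(pts[idx])
            if cc is None:
                continue
            (cy, cx), cr = cc
            circle = EllipseParams(cy=cy, cx=cx, r=max(cr, 1.0),
                                   ratio_min=ratio_min)
            if not _clamp_ok(circle, bbox) or _center_background(
                circle, background_mask
            ):
                continue
            init = EllipseParams(
                cy=cy, cx=cx, r=max(cr, 1.0), eps=eps0,
                theta=rng.uniform(0.0, np.pi), ratio_min=ratio_min,
            )
            fit, fval = _refine(init, pts, sigma)
            if not _clamp_ok(fit, bbox) or _center_background(
                fit, background_mask
            ):
                continue
            # normalise by support so large ellipses are not penalised
            score = fval / len(pts)
            if best is None or score < best[0]:
                best = (score, fit)
        if best is None:
            break
        fit = best[1]
        res = np.abs(normalized_error(fit, contour.pixels.astype(float)))
        consume = (~contour.removed) & (res < removal_sigma)
        n_consumed = int(consume.sum())
        if n_consumed == 0:
            break
        contour.removed |= consume
        a, b = fit.semi_axes
        expected_pixels = ramanujan_perimeter(a, b) * sigma
        if 2.0 * b < min_width or n_consumed < min_consumed_fraction * expected_pixels:
            continue  # reject the ellipse; its pixels stay consumed
        accepted.append(_inflate(fit, sigma / 2.0))
    return accepted


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the ellipse perimeter.

    pi [3 (a + b) - sqrt((3a + b)(a + 3b))] for semi-axes a >= b > 0;
    exact 2 pi r in the circle limit.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    return float(np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b))))
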