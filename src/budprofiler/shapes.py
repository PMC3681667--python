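"""Cell shapes from watershed basins, and mother/bud/lone typing.

Cells are rarely exactly elliptical, so the final cell areas ("shapes") are
assembled from watershed catchment basins of the RFP intensity: every basin
is assigned to the fitted ellipse whose algebraic error at the basin's
brightest pixel is smallest, and a shape is the union of the basins owned
by one ellipse.  Because basin boundaries sit on dim pixels, boundaries
between cells automatically fall in the dim gaps.

Types follow the reciprocal-extremum heuristic: a mother-bud pair is a pair
of adjacent shapes that are reciprocally each other's largest and smallest
neighbours, where the bud additionally has no smaller neighbour of its own;
everything else is a lone cell.  The bud neck is the set of pixels of the
pair with an 8-neighbour in the partner shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ellipse import EllipseParams, algebraic_error

__all__ = [
    "CellShape",
    "TypedCell",
    "watershed_basins",
    "assemble_shapes",
    "assign_cell_types",
    "shape_label_map",
]

_NEIGHBORS8 = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)
)


@dataclass
class CellShape:
    """A set of foreground pixels forming one candidate cell."""

    pixels: np.ndarray  # (n, 2) int (row, col)
    shape_id: int
    ellipse_id: int | None = None
    clump_id: int = 0
    fit_residual: float = 0.0  # per-pixel residual of the owning ellipse fit

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


@dataclass
class TypedCell:
    """A shape with its assigned type and mother/bud bookkeeping.

    ``bud_area`` is the cell-stage covariate: the bud's own area for buds,
    the partner bud's area for mothers, None for lone cells.
    """

    shape: CellShape
    cell_type: str  # 'mother' | 'bud' | 'lone'
    partner_id: int | None = None
    neck_pixels: np.ndarray | None = None
    neck_position: np.ndarray | None = None
    bud_area: int | None = None
    tie_flagged: bool = False


def watershed_basins(rfp: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Label foreground pixels by steepest-ascent catchment basin.

    Every foreground pixel follows its strictly-greatest 8-neighbour (ties
    between equal greatest neighbours are broken by a fixed neighbour
    order) until it reaches a pixel brighter than all of its neighbours;
    pixels reaching the same maximum (plateau maxima are merged by
    8-connectivity) share a basin label.  Background pixels are labelled 0.
    """
    rfp = np.asarray(rfp, dtype=float)
    fg = np.asarray(foreground, dtype=bool)
    if rfp.shape != fg.shape:
        raise ValueError("intensity and mask shapes differ")
    if not fg.any():
        return np.zeros(rfp.shape, dtype=int)
    h, w = rfp.shape
    val = np.where(fg, rfp, -np.inf)
    flat = np.arange(h * w).reshape(h, w)
    parent = flat.copy()
    best_val = val.copy()
    for dr, dc in _NEIGHBORS8:
        shifted = np.full((h, w), -np.inf)
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        shifted[r0:r1, c0:c1] = val[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        nbr_idx = np.full((h, w), -1)
        nbr_idx[r0:r1, c0:c1] = flat[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        better = shifted > best_val  # strict: first neighbour in order wins ties
        parent[better] = nbr_idx[better]
        best_val[better] = shifted[better]
    parent = parent.ravel()
    while True:
        grand = parent[parent]
        if np.array_equal(grand, parent):
            break
        parent = grand
    roots = (parent == np.arange(h * w)).reshape(h, w) & fg
    root_labels, _ = ndimage.label(roots, structure=np.ones((3, 3), dtype=int))
    labels = root_labels.ravel()[parent].reshape(h, w)
    labels[~fg] = 0
    return labels


def assemble_shapes(
    basins: np.ndarray,
    ellipses: list[EllipseParams],
    rfp: np.ndarray,
    clump_id: int = 0,
    id_offset: int = 0,
) -> tuple[list[CellShape], list[np.ndarray]]:
    """Assign basins to ellipses and union same-ellipse basins into shapes.

    Each basin is owned by the ellipse with the smallest |algebraic error|
    at the basin's maximum-intensity pixel.  Returns the shapes plus the
    pixel sets of basins that could not be assigned (no ellipse supplied),
    which go to the artifact pool.
    """
    basins = np.asarray(basins)
    rfp = np.asarray(rfp, dtype=float)
    basin_ids = np.unique(basins)
    basin_ids = basin_ids[basin_ids > 0]
    if len(basin_ids) == 0:
        return [], []
    if not ellipses:
        return [], [np.argwhere(basins == b) for b in basin_ids]
    assignment: dict[int, list[np.ndarray]] = {}
    resid: dict[int, list[float]] = {}
    for b in basin_ids:
        pix = np.argwhere(basins == b)
        peak = pix[np.argmax(rfp[pix[:, 0], pix[:, 1]])]
        errs = np.array(
            [abs(algebraic_error(e, peak.astype(float))) for e in ellipses]
        )
        owner = int(np.argmin(errs))
        assignment.setdefault(owner, []).append(pix)
        resid.setdefault(owner, []).append(float(errs[owner]))
    shapes = []
    for owner in sorted(assignment):
        pixels = np.vstack(assignment[owner])
        shapes.append(
            CellShape(
                pixels=pixels,
                shape_id=id_offset + len(shapes),
                ellipse_id=owner,
                clump_id=clump_id,
                fit_residual=float(np.mean(resid[owner])),
            )
        )
    return shapes, []


def shape_label_map(shapes: list[CellShape], shape_hw: tuple[int, int]) -> np.ndarray:
    """Label image of shape ids + 1 (0 = no shape)."""
    out = np.zeros(shape_hw, dtype=int)
    for s in shapes:
        out[s.pixels[:, 0], s.pixels[:, 1]] = s.shape_id + 1
    return out


def _adjacency(label_map: np.ndarray) -> dict[int, set[int]]:
    """Pairs of shape labels sharing >= 1 8-connected cross-boundary pixels."""
    adj: dict[int, set[int]] = {}
    h, w = label_map.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        a = label_map[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        b = label_map[r0:r1, c0:c1]
        touching = (a > 0) & (b > 0) & (a != b)
        for la, lb in zip(a[touching].ravel(), b[touching].ravel()):
            adj.setdefault(int(la) - 1, set()).add(int(lb) - 1)
            adj.setdefault(int(lb) - 1, set()).add(int(la) - 1)
    return adj


def _neck(label_map: np.ndarray, id_a: int, id_b: int) -> np.ndarray:
    """Pixels of either shape with an 8-neighbour in the other shape."""
    a = label_map == id_a + 1
    b = label_map == id_b + 1
    st = np.ones((3, 3), dtype=bool)
    touch_a = a & ndimage.binary_dilation(b, structure=st)
    touch_b = b & ndimage.binary_dilation(a, structure=st)
    return np.argwhere(touch_a | touch_b)


def assign_cell_types(
    shapes: list[CellShape], shape_hw: tuple[int, int]
) -> list[TypedCell]:
    """Type each shape as mother, bud or lone.

    A pair (M, B) requires: B is M's smallest neighbour, M is B's largest
    neighbour, and B has no neighbour smaller than itself.  Size ties are
    broken by smaller ellipse-fit residual, then lower shape id (flagged).
    The result is independent of the order the shapes are supplied in.
    """
    shapes = sorted(shapes, key=lambda s: s.shape_id)
    by_id = {s.shape_id: s for s in shapes}
    label_map = shape_label_map(shapes, shape_hw)
    adj = _adjacency(label_map)

    def sort_key(sid: int):
        s = by_id[sid]
        return (s.area, s.fit_residual, s.shape_id)

    tie_flag: set[int] = set()

    def extremum(neighbors: set[int], smallest: bool) -> int | None:
        if not neighbors:
            return None
        ordered = sorted(neighbors, key=sort_key, reverse=not smallest)
        if len(ordered) > 1 and by_id[ordered[0]].area == by_id[ordered[1]].area:
            tie_flag.add(ordered[0])
        return ordered[0]

    candidate_pairs = []
    for sid, nbrs in adj.items():
        b = extremum(nbrs, smallest=True)
        if b is None:
            continue
        # bud must have no smaller neighbour, and its largest neighbour must be sid
        b_nbrs = adj.get(b, set())
        if extremum(b_nbrs, smallest=False) != sid:
            continue
        if any(by_id[x].area < by_id[b].area for x in b_nbrs):
            continue
        candidate_pairs.append((sid, b))
    used: set[int] = set()
    cells: dict[int, TypedCell] = {}
    for mother, bud in sorted(
        candidate_pairs, key=lambda p: (by_id[p[1]].area, p[1], p[0])
    ):
        if mother in used or bud in used:
            continue
        used.update((mother, bud))
        neck = _neck(label_map, mother, bud)
        neck_pos = neck.mean(axis=0) if len(neck) else None
        bud_area = by_id[bud].area
        cells[mother] = TypedCell(
            shape=by_id[mother], cell_type="mother", partner_id=bud,
            neck_pixels=neck, neck_position=neck_pos, bud_area=bud_area,
            tie_flagged=mother in tie_flag or bud in tie_flag,
        )
        cells[bud] = TypedCell(
            shape=by_id[bud], cell_type="bud", partner_id=mother,
            neck_pixels=neck, neck_position=neck_pos, bud_area=bud_area,
            tie_flagged=mother in tie_flag or bud in tie_flag,
        )
    for s in shapes:
        if s.shape_id not in cells:
            cells[s.shape_id] = TypedCell(shape=s, cell_type="lone")
    return [cells[s.shape_id] for s in shapes]
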