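"""Synthetic two-channel yeast micrographs with full ground truth.

Emulates the structure of high-resolution RFP/GFP micrographs of budding
yeast: ellipsoidal cells with per-cell marker levels, clumps whose
inter-cell boundaries are dimmer than both flanking interiors, vacuole
dimming, mother-attached buds spanning a range of sizes (the cell-stage
clock), structured GFP expression patterns, camera background noise and a
small bestiary of artifact objects.  Everything is generated from a seeded
RNG, so identical config + seed gives a bit-identical scene, and the full
ground truth (masks, ellipse parameters, pairings, pattern labels) is
returned for evaluation.

Also provides the profile-collection generator used to exercise the
clustering stages, and the detection-evaluation protocol that matches
identified objects to ground truth within a pixel radius.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .profiles import PROFILE_LENGTH
from .segmentation import Micrograph

__all__ = [
    "GfpPatternSpec",
    "SceneConfig",
    "TrueCell",
    "GroundTruth",
    "DetectionReport",
    "PlacementError",
    "simulate_micrograph",
    "simulate_profile_collection",
    "evaluate_detection",
    "write_scene",
    "GFP_KINDS",
]

GFP_KINDS = (
    "uniform",
    "nuclear-disc",
    "peripheral-ring",
    "bud-neck-spot",
    "punctate",
    "stage-switching",
)

ARTIFACT_KINDS = ("edge_noise", "ruptured", "dim", "defective_pixel")

MAX_VALUE = 4095.0  # 12-bit range stored in 16-bit containers


class PlacementError(RuntimeError):
    """A cell could not be placed within the retry budget."""


@dataclass
class GfpPatternSpec:
    """Spatial GFP expression pattern of one simulated protein.

    ``stage-switching`` proteins render ``kind_small`` while the bud area
    is below ``stage_switch_area`` and ``kind_large`` above (emulating
    relocalisation during bud growth); lone cells use ``kind_large``.
    """

    kind: str = "uniform"
    amplitude: float = 300.0
    stage_switch_area: float | None = None
    kind_small: str = "peripheral-ring"
    kind_large: str = "bud-neck-spot"
    n_puncta: int = 4

    def __post_init__(self) -> None:
        if self.kind not in GFP_KINDS:
            raise ValueError(f"unknown GFP pattern kind {self.kind!r}")
        if self.kind == "stage-switching" and self.stage_switch_area is None:
            self.stage_switch_area = 120.0


@dataclass
class SceneConfig:
    """Parameters of one simulated micrograph scene."""

    height: int = 192
    width: int = 192
    n_cells: int = 12
    cell_area_range: tuple[float, float] = (250.0, 700.0)
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)
    clump_fraction: float = 0.5
    bud_fraction: float = 0.4
    bud_area_range: tuple[float, float] = (30.0, 260.0)
    rfp_level_range: tuple[float, float] = (500.0, 1200.0)
    vacuole_prob: float = 0.3
    vacuole_depth: float = 0.4
    background_mean: float = 100.0
    background_sd: float = 20.0
    boundary_dim: float = 0.3
    blur_sigma: float = 1.0  # FWHM ~2.4 px edge roll-off
    artifact_count: int = 2
    artifact_kinds: tuple[str, ...] = ARTIFACT_KINDS
    gfp_pattern: GfpPatternSpec = field(default_factory=GfpPatternSpec)
    seed: int = 0
    max_retries: int = 500

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.artifact_count < 0:
            raise ValueError("counts must be >= 0")
        if self.background_sd <= 0:
            raise ValueError("noise sd must be > 0")
        for name in ("clump_fraction", "bud_fraction", "vacuole_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for kind in self.artifact_kinds:
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {kind!r}")
        if isinstance(self.gfp_pattern, dict):
            self.gfp_pattern = GfpPatternSpec(**self.gfp_pattern)


@dataclass
class TrueCell:
    """Ground-truth record of one simulated cell."""

    index: int
    center: np.ndarray  # (row, col)
    semi_major: float
    semi_minor: float
    theta: float
    rfp_level: float
    cell_type: str = "lone"  # 'mother' | 'bud' | 'lone'
    mother: int | None = None
    bud_area: int | None = None  # rasterised pixel count of the bud
    neck: np.ndarray | None = None
    pattern_label: str = "uniform"

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.semi_major * self.semi_minor))


@dataclass
class GroundTruth:
    """Full ground truth of a simulated scene.

    ``label_map`` holds cell index + 1 per pixel (0 = background); masks
    are therefore disjoint by construction.  Every bud has exactly one
    mother, and ``bud_area`` equals the bud's mask pixel count.
    """

    cells: list[TrueCell]
    label_map: np.ndarray
    artifact_mask: np.ndarray
    artifact_kinds_placed: list[str] = field(default_factory=list)

    def mask(self, index: int) -> np.ndarray:
        return self.label_map == index + 1

    def areas(self) -> np.ndarray:
        if not self.cells:
            return np.zeros(0)
        return np.bincount(
            self.label_map.ravel(), minlength=len(self.cells) + 1
        )[1:len(self.cells) + 1].astype(float)

    def centers(self) -> np.ndarray:
        if not self.cells:
            return np.zeros((0, 2))
        return np.vstack([c.center for c in self.cells])


def _quad_form(cell: TrueCell, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Normalised ellipse quadratic q: q <= 1 inside, 1 on the boundary."""
    dy = rows - cell.center[0]
    dx = cols - cell.center[1]
    ct, st = np.cos(cell.theta), np.sin(cell.theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return (u / cell.semi_major) ** 2 + (v / cell.semi_minor) ** 2


def _sample_axes(rng: np.random.Generator, cfg: SceneConfig, area: float):
    ratio = rng.uniform(*cfg.axis_ratio_range)
    a = np.sqrt(area / (np.pi * ratio))
    return a, ratio * a


def _place_cells(rng: np.random.Generator, cfg: SceneConfig) -> list[TrueCell]:
    cells: list[TrueCell] = []
    h, w = cfg.height, cfg.width

    def too_close(center, radius, skip=None) -> bool:
        for j, other in enumerate(cells):
            if j == skip:
                continue
            if np.linalg.norm(center - other.center) < 1.02 * (
                radius + other.radius
            ):
                return True
        return False

    for i in range(cfg.n_cells):
        area = rng.uniform(*cfg.cell_area_range)
        a, b = _sample_axes(rng, cfg, area)
        radius = float(np.sqrt(a * b))
        placed = False
        for _ in range(cfg.max_retries):
            if cells and rng.random() < cfg.clump_fraction:
                anchor = cells[rng.integers(len(cells))]
                ang = rng.uniform(0, 2 * np.pi)
                center = anchor.center + 0.98 * (radius + anchor.radius) * np.array(
                    [np.sin(ang), np.cos(ang)]
                )
                skip = anchor.index
            else:
                margin = radius + 3.0
                if h - 2 * margin <= 0 or w - 2 * margin <= 0:
                    raise PlacementError(
                        "cell_area_range too large for the image size"
                    )
                center = np.array(
                    [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
                )
                skip = None
            if (
                center[0] < radius or center[0] > h - radius
                or center[1] < radius or center[1] > w - radius
            ):
                continue
            if not too_close(center, radius, skip=skip):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i}; lower n_cells or cell_area_range"
            )
        cells.append(
            TrueCell(
                index=i, center=center, semi_major=float(a),
                semi_minor=float(b), theta=float(rng.uniform(0, np.pi)),
                rfp_level=float(rng.uniform(*cfg.rfp_level_range)),
            )
        )
    return cells


def _attach_buds(rng: np.random.Generator, cfg: SceneConfig, cells) -> None:
    """Turn a fraction of placed cells into mothers with attached buds.

    Bud areas are stratified across the configured range so that the
    ground truth spans the full cell-stage axis.
    """
    n_mothers = int(round(cfg.bud_fraction * cfg.n_cells))
    if n_mothers == 0:
        return
    h, w = cfg.height, cfg.width
    lo, hi = cfg.bud_area_range
    strata = np.linspace(lo, hi, n_mothers + 1)
    mother_idx = list(rng.permutation(len(cells))[:n_mothers])
    for m_pos, mi in enumerate(mother_idx):
        mother = cells[mi]
        area = rng.uniform(strata[m_pos], strata[m_pos + 1])
        r_bud = float(np.sqrt(area / np.pi))
        placed = False
        for _ in range(cfg.max_retries):
            ang = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.sin(ang), np.cos(ang)])
            center = mother.center + 0.92 * (mother.radius + r_bud) * direction
            if (
                center[0] < r_bud + 1 or center[0] > h - r_bud - 1
                or center[1] < r_bud + 1 or center[1] > w - r_bud - 1
            ):
                continue
            ok = True
            for other in cells:
                if other.index == mother.index:
                    continue
                if np.linalg.norm(center - other.center) < 1.02 * (
                    r_bud + other.radius
                ):
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            continue  # mother stays lone; bud fraction is a target, not a vow
        bud = TrueCell(
            index=len(cells), center=center, semi_major=r_bud,
            semi_minor=r_bud, theta=0.0,
            rfp_level=float(rng.uniform(*cfg.rfp_level_range)),
            cell_type="bud", mother=mother.index,
        )
        mother.cell_type = "mother"
        neck = 0.5 * (
            mother.center + mother.radius * direction
            + (center - r_bud * direction)
        )
        mother.neck = bud.neck = neck
        cells.append(bud)


def simulate_micrograph(config: SceneConfig) -> tuple[Micrograph, GroundTruth]:
    """Render one two-channel scene with its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    cells = _place_cells(rng, cfg)
    _attach_buds(rng, cfg, cells)

    # rasterise: each pixel goes to the cell with the smallest normalised
    # quadratic, provided it is inside that ellipse -> disjoint masks
    label_map = np.zeros((h, w), dtype=int)
    best_q = np.full((h, w), np.inf)
    for cell in cells:
        q = _quad_form(cell, rows, cols)
        take = (q <= 1.0) & (q < best_q)
        label_map[take] = cell.index + 1
        best_q[take] = q[take]

    # record bud areas and re-derive necks from the rasterised masks
    for cell in cells:
        if cell.cell_type == "bud":
            area = int(np.count_nonzero(label_map == cell.index + 1))
            cell.bud_area = area
            cells[cell.mother].bud_area = area

    # RFP: per-cell level with a gentle radial roll-off, vacuole dimming
    rfp_signal = np.zeros((h, w))
    for cell in cells:
        mask = label_map == cell.index + 1
        if not mask.any():
            continue
        q = _quad_form(cell, rows, cols)
        intensity = cell.rfp_level * (1.0 - 0.25 * np.clip(q, 0, 1))
        if rng.random() < cfg.vacuole_prob:
            off = 0.3 * cell.radius * np.array(
                [rng.uniform(-1, 1), rng.uniform(-1, 1)]
            )
            vac_r = 0.4 * cell.radius
            vac = (rows - cell.center[0] - off[0]) ** 2 + (
                cols - cell.center[1] - off[1]
            ) ** 2 <= vac_r**2
            intensity = np.where(vac, intensity * (1.0 - cfg.vacuole_depth),
                                 intensity)
        rfp_signal[mask] = intensity[mask]

    # dim inter-cell boundaries (pixels whose 8-neighbourhood crosses two
    # different cells), widened by one pixel so the valley survives the blur
    boundary = np.zeros((h, w), dtype=bool)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = label_map[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)]
        b = label_map[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)]
        cross = (a > 0) & (b > 0) & (a != b)
        boundary[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)] |= cross
        boundary[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)] |= cross
    boundary = binary_dilation(boundary, structure=np.ones((3, 3), bool))
    rfp_signal[boundary] *= cfg.boundary_dim

    # artifacts (RFP channel), placed on free background
    artifact_mask = np.zeros((h, w), dtype=bool)
    placed_kinds: list[str] = []
    defective_pixels: list[tuple[int, int]] = []
    for k in range(cfg.artifact_count):
        kind = cfg.artifact_kinds[k % len(cfg.artifact_kinds)]
        for _ in range(cfg.max_retries):
            if kind == "edge_noise":
                corner = rng.integers(4)
                cy = rng.uniform(0, 8) if corner < 2 else rng.uniform(h - 8, h)
                cx = rng.uniform(0, 8) if corner % 2 == 0 else rng.uniform(w - 8, w)
                rad = rng.uniform(6, 12)
                blob = (rows - cy) ** 2 + (cols - cx) ** 2 <= rad**2
                blob &= label_map == 0
                if blob.sum() < 10:
                    continue
                rfp_signal[blob] += rng.uniform(*cfg.rfp_level_range)
                artifact_mask |= blob
                break
            cy = rng.uniform(15, h - 15)
            cx = rng.uniform(15, w - 15)
            rad = rng.uniform(6, 11)
            disc = (rows - cy) ** 2 + (cols - cx) ** 2 <= rad**2
            if (label_map[disc] > 0).any() or artifact_mask[disc].any():
                continue
            if kind == "ruptured":
                hole = (rows - cy) ** 2 + (cols - cx) ** 2 <= (0.55 * rad) ** 2
                ring = disc & ~hole
                rfp_signal[ring] += 0.6 * np.mean(cfg.rfp_level_range)
                artifact_mask |= ring
            elif kind == "dim":
                rfp_signal[disc] += 1.5 * cfg.background_sd
                artifact_mask |= disc
            elif kind == "defective_pixel":
                r_i, c_i = int(cy), int(cx)
                defective_pixels.append((r_i, c_i))
                artifact_mask[r_i, c_i] = True
            break
        else:
            continue
        placed_kinds.append(kind)

    rfp = gaussian_filter(rfp_signal, cfg.blur_sigma)
    rfp += rng.normal(cfg.background_mean, cfg.background_sd, size=(h, w))
    for r_i, c_i in defective_pixels:
        rfp[r_i, c_i] = MAX_VALUE
    rfp = np.clip(rfp, 0.0, MAX_VALUE)

    gfp_signal = _render_gfp(rng, cfg, cells, label_map, rows, cols)
    gfp = gaussian_filter(gfp_signal, min(cfg.blur_sigma, 1.0))
    gfp += rng.normal(cfg.background_mean, cfg.background_sd, size=(h, w))
    gfp = np.clip(gfp, 0.0, MAX_VALUE)

    truth = GroundTruth(
        cells=cells, label_map=label_map, artifact_mask=artifact_mask,
        artifact_kinds_placed=placed_kinds,
    )
    return Micrograph(rfp=rfp, gfp=gfp, source=f"synthetic-seed{cfg.seed}"), truth


def _render_gfp(rng, cfg, cells, label_map, rows, cols) -> np.ndarray:
    spec = cfg.gfp_pattern
    gfp = np.zeros(label_map.shape)
    for cell in cells:
        mask = label_map == cell.index + 1
        if not mask.any():
            continue
        kind = spec.kind
        if kind == "stage-switching":
            if cell.bud_area is not None and cell.bud_area < spec.stage_switch_area:
                kind = spec.kind_small
            else:
                kind = spec.kind_large
        cell.pattern_label = kind
        amp = spec.amplitude
        q = _quad_form(cell, rows, cols)
        if kind == "uniform":
            gfp[mask] += amp
            continue
        gfp[mask] += 0.15 * amp  # faint cytosolic haze under structured signal
        if kind == "nuclear-disc":
            off = 0.2 * cell.radius * np.array([rng.uniform(-1, 1), rng.uniform(-1, 1)])
            nuc = (rows - cell.center[0] - off[0]) ** 2 + (
                cols - cell.center[1] - off[1]
            ) ** 2 <= (0.35 * cell.radius) ** 2
            gfp[mask & nuc] += 3.0 * amp
        elif kind == "peripheral-ring":
            ring = mask & (q >= 0.6)
            gfp[ring] += 3.0 * amp
        elif kind == "bud-neck-spot":
            target = cell.neck if cell.neck is not None else cell.center
            spot = np.exp(
                -((rows - target[0]) ** 2 + (cols - target[1]) ** 2) / (2 * 2.0**2)
            )
            gfp[mask] += 4.0 * amp * spot[mask]
        elif kind == "punctate":
            pix = np.argwhere(mask)
            for _ in range(spec.n_puncta):
                pr, pc = pix[rng.integers(len(pix))]
                spot = np.exp(
                    -((rows - pr) ** 2 + (cols - pc) ** 2) / (2 * 1.2**2)
                )
                gfp[mask] += 4.0 * amp * spot[mask]
        else:
            raise ValueError(f"unknown GFP pattern kind {kind!r}")
    return gfp


def simulate_profile_collection(
    class_defs: list[tuple[np.ndarray, np.ndarray, int]],
    seed: int = 0,
    profile_length: int = PROFILE_LENGTH,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw protein profiles around class means.

    Each class is (mean profile, sd profile, member count), profiles of
    length 120; a member's profile is the class mean plus Gaussian noise
    scaled by the sd profile.  Returns (means, variances, class labels);
    the variance table carries the squared sd profile, the within-class
    spread a LOESS fit would report.
    """
    rng = np.random.default_rng(seed)
    means, variances, labels, index = [], [], [], []
    for c, (mu, sd, size) in enumerate(class_defs):
        mu = np.asarray(mu, dtype=float)
        sd = np.asarray(sd, dtype=float)
        if mu.shape != (profile_length,) or sd.shape != (profile_length,):
            raise ValueError(
                f"class {c}: profiles must have length {profile_length}"
            )
        for m in range(int(size)):
            means.append(mu + sd * rng.standard_normal(profile_length))
            variances.append(sd**2)
            labels.append(c)
            index.append(f"class{c}_p{m}")
    cols = [f"v{j}" for j in range(profile_length)]
    return (
        pd.DataFrame(means, index=index, columns=cols),
        pd.DataFrame(variances, index=index, columns=cols),
        pd.Series(labels, index=index, name="class"),
    )


@dataclass
class DetectionReport:
    """Outcome of matching detected objects against ground truth."""

    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    mean_center_distance: float
    area_correlation: float
    false_positive_rate: float
    n_artifact_matches: int
    undefined: bool = False


def evaluate_detection(
    detected_centers: np.ndarray,
    detected_areas: np.ndarray,
    truth: GroundTruth,
    radius: float = 10.0,
) -> DetectionReport:
    """Greedy one-to-one matching of detections to ground-truth cells.

    All truth-detection pairs within ``radius`` pixels are considered in
    order of increasing centre distance; each side is matched at most
    once.  Reports recall, the mean matched-centre distance, the Pearson
    correlation of matched areas, the unmatched-detection rate, and how
    many unmatched detections sit on artifact pixels.  Empty truth leaves
    recall undefined (flagged).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    detected_centers = np.asarray(detected_centers, dtype=float).reshape(-1, 2)
    detected_areas = np.asarray(detected_areas, dtype=float).ravel()
    t_centers = truth.centers()
    t_areas = truth.areas()
    n_t, n_d = len(t_centers), len(detected_centers)
    if n_t == 0:
        return DetectionReport(
            n_truth=0, n_detected=n_d, n_matched=0, recall=float("nan"),
            mean_center_distance=float("nan"), area_correlation=float("nan"),
            false_positive_rate=float(n_d > 0), n_artifact_matches=0,
            undefined=True,
        )
    pairs = []
    for i in range(n_t):
        d = np.linalg.norm(detected_centers - t_centers[i], axis=1)
        for j in np.nonzero(d <= radius)[0]:
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for d, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j, d))
    n_m = len(matches)
    recall = n_m / n_t
    mean_dist = float(np.mean([d for _, _, d in matches])) if n_m else float("nan")
    if n_m >= 2:
        ta = np.array([t_areas[i] for i, _, _ in matches])
        da = np.array([detected_areas[j] for _, j, _ in matches])
        area_corr = (
            float(np.corrcoef(ta, da)[0, 1])
            if np.std(ta) > 0 and np.std(da) > 0 else float("nan")
        )
    else:
        area_corr = float("nan")
    unmatched = [j for j in range(n_d) if j not in used_d]
    fpr = len(unmatched) / n_d if n_d else 0.0
    n_art = 0
    h, w = truth.artifact_mask.shape
    for j in unmatched:
        r, c = (int(round(v)) for v in detected_centers[j])
        if 0 <= r < h and 0 <= c < w and truth.artifact_mask[r, c]:
            n_art += 1
    return DetectionReport(
        n_truth=n_t, n_detected=n_d, n_matched=n_m, recall=recall,
        mean_center_distance=mean_dist, area_correlation=area_corr,
        false_positive_rate=float(fpr), n_artifact_matches=n_art,
    )


def write_scene(
    out_dir: str | Path,
    mic: Micrograph,
    truth: GroundTruth,
    config: SceneConfig,
    stem: str = "scene",
) -> dict[str, Path]:
    """Write paired TIFFs, a ground-truth TSV and a JSON scene manifest."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rfp": out / f"{stem}_rfp.tif",
        "gfp": out / f"{stem}_gfp.tif",
        "truth": out / f"{stem}_truth.tsv",
        "manifest": out / f"{stem}_manifest.json",
    }
    tifffile.imwrite(paths["rfp"], np.round(mic.rfp).astype(np.uint16))
    tifffile.imwrite(paths["gfp"], np.round(mic.gfp).astype(np.uint16))
    rows = []
    for c in truth.cells:
        rows.append(
            {
                "cell": c.index, "row": c.center[0], "col": c.center[1],
                "semi_major": c.semi_major, "semi_minor": c.semi_minor,
                "theta": c.theta, "type": c.cell_type,
                "mother": -1 if c.mother is None else c.mother,
                "bud_area": -1 if c.bud_area is None else c.bud_area,
                "neck_row": float("nan") if c.neck is None else c.neck[0],
                "neck_col": float("nan") if c.neck is None else c.neck[1],
                "pattern": c.pattern_label,
            }
        )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    cfg = dataclasses.asdict(config)
    cfg["gfp_pattern"] = dataclasses.asdict(config.gfp_pattern)
    paths["manifest"].write_text(json.dumps(cfg, indent=2, default=str))
    return paths
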