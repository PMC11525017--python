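"""Synthetic brightfield H-DAB TMA core images and a classical single-cell
caller.

The renderer composes per-pixel optical densities (OD) for the hematoxylin
counterstain and the DAB chromogen from elliptical nuclei, tissue-fold
artifact bands and background wash, then converts OD to RGB transmission via
Beer-Lambert with fixed unit stain vectors.  Every rendered nucleus carries
ground truth (class, positivity, label-mask id), so the caller can be scored
exactly.

The caller inverts the same physics: color deconvolution with the stain
matrix, nucleus detection on the summed OD (smoothing, thresholding,
distance-transform watershed to split touching nuclei), then class assignment
from morphology (area, eccentricity) and DAB positivity from mean nuclear
DAB OD.  It is a fully specified classical stand-in for a trained
segmentation/phenotyping model, not a reproduction of one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .cohort import CLASS_COLUMNS

#: unit stain OD vectors (rows), standard H-DAB values
HEMATOXYLIN_VECTOR = np.array([0.65, 0.70, 0.29])
DAB_VECTOR = np.array([0.27, 0.57, 0.78])

NUCLEUS_CLASSES = (
    "positive_tumor", "negative_tumor", "positive_stromal", "negative_stromal",
    "lymphocyte", "strong_background", "weak_background",
)


def default_stain_matrix() -> np.ndarray:
    """3x3 stain matrix: rows hematoxylin, DAB, residual (unit vectors)."""
    h = HEMATOXYLIN_VECTOR / np.linalg.norm(HEMATOXYLIN_VECTOR)
    d = DAB_VECTOR / np.linalg.norm(DAB_VECTOR)
    r = np.cross(h, d)
    r /= np.linalg.norm(r)
    return np.stack([h, d, r])


@dataclass
class Nucleus:
    y: float
    x: float
    ry: float          # semi-axis along the rotated minor direction
    rx: float          # semi-axis along the rotated major direction
    theta: float       # orientation, radians
    cls: str           # one of NUCLEUS_CLASSES
    dab_od: float
    hem_od: float


@dataclass
class CoreImageSpec:
    diameter: int = 360
    margin: int = 12
    nuclei: list = field(default_factory=list)
    fold_bands: list = field(default_factory=list)  # (angle, offset, width)
    background_wash: float = 0.06
    noise_sd: float = 0.01
    seed: int = 0

    @property
    def size(self) -> int:
        return self.diameter + 2 * self.margin


@dataclass
class RenderedCore:
    rgb: np.ndarray     # uint8 (H, W, 3)
    mask: np.ndarray    # int32 nucleus ids, 0 = background
    truth: pd.DataFrame  # per-nucleus id, class, positivity, centroid, area


def _ellipse_mask(shape, y, x, ry, rx, theta):
    r0 = max(int(y - rx - ry - 2), 0)
    r1 = min(int(y + rx + ry + 3), shape[0])
    c0 = max(int(x - rx - ry - 2), 0)
    c1 = min(int(x + rx + ry + 3), shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - y, xx - x
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / rx
    v = (-dx * st + dy * ct) / ry
    return (slice(r0, r1), slice(c0, c1)), (u * u + v * v) <= 1.0


def render_core(spec: CoreImageSpec) -> RenderedCore:
    """Render a core to RGB by Beer-Lambert transmission of summed stain ODs.

    Nuclei are opaque: where they overlap, the first-listed nucleus wins both
    the label mask and the stain OD.  Raises if the summed nucleus area
    exceeds 60% of the core disc (unrealistic packing).
    """
    size = spec.size
    center = size / 2.0
    radius = spec.diameter / 2.0

    disc_area = math.pi * radius * radius
    nuc_area = sum(math.pi * n.ry * n.rx for n in spec.nuclei)
    if nuc_area > 0.6 * disc_area:
        raise ValueError(
            f"requested nuclei cover {nuc_area / disc_area:.0%} of the core; packing limit is 60%"
        )

    yy, xx = np.mgrid[0:size, 0:size]
    disc = (yy - center) ** 2 + (xx - center) ** 2 <= radius * radius

    od_h = np.zeros((size, size))
    od_d = np.zeros((size, size))
    rng = np.random.default_rng(spec.seed)
    od_h[disc] = spec.background_wash
    if spec.noise_sd > 0:
        texture = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), 2.0)
        od_h += np.where(disc, spec.noise_sd * texture, 0.0)
        od_h = np.clip(od_h, 0, None)

    mask = np.zeros((size, size), dtype=np.int32)
    truth_rows = []
    for i, n in enumerate(spec.nuclei, start=1):
        sl, em = _ellipse_mask(mask.shape, n.y, n.x, n.ry, n.rx, n.theta)
        free = em & (mask[sl] == 0)
        mask[sl][free] = i
        region_h, region_d = od_h[sl], od_d[sl]
        region_h[free] = n.hem_od
        region_d[free] = n.dab_od
        positive = n.cls.startswith("positive") or (n.cls == "lymphocyte" and n.dab_od >= 0.3)
        truth_rows.append(
            {"nucleus_id": i, "y": n.y, "x": n.x, "cls": n.cls,
             "positive": bool(positive), "area": int(free.sum())}
        )

    for angle, offset, width in spec.fold_bands:
        ct, st = math.cos(angle), math.sin(angle)
        dist = (xx - center) * ct + (yy - center) * st - offset
        band = (np.abs(dist) <= width / 2.0) & disc
        od_h[band] = np.maximum(od_h[band], 0.8)
        od_d[band] = np.maximum(od_d[band], 0.9)
        mask[band] = 0  # folds obscure underlying nuclei

    stains = default_stain_matrix()
    od_rgb = od_h[..., None] * stains[0] + od_d[..., None] * stains[1]
    rgb = np.clip(np.rint(255.0 * 10.0 ** (-od_rgb)), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(truth_rows, columns=["nucleus_id", "y", "x", "cls", "positive", "area"])
    return RenderedCore(rgb, mask, truth)


def deconvolve_stains(rgb: np.ndarray, stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Unmix an RGB image into (hematoxylin, DAB, residual) OD channels.

    OD = -log10(I / I0) with I0 = 255; channels solve  od_rgb = channels @ M
    for the given stain matrix M (rows = unit stain vectors).
    """
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    M = default_stain_matrix() if stain_matrix is None else np.asarray(stain_matrix, dtype=float)
    if M.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3 (rows = stain vectors)")
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0) or np.linalg.cond(M / norms[:, None]) > 1e6:
        raise ValueError("stain matrix is singular or near-singular")
    intensity = np.maximum(rgb.astype(float), 1.0)
    od_rgb = -np.log10(intensity / 255.0)
    return od_rgb @ np.linalg.inv(M)


@dataclass
class CallParams:
    detect_threshold: float = 0.22   # on smoothed H+DAB OD
    smooth_sigma: float = 0.8
    min_area: int = 8                # px^2, smaller detections discarded
    watershed_min_distance: int = 4
    positivity_cutoff: float = 0.15  # mean nuclear DAB OD
    split_min_area: int = 150        # px^2: only larger components are
                                     # watershed-split (protects thin stromal
                                     # nuclei from being chopped into chunks)
    stromal_eccentricity: float = 0.78
    lymphocyte_eccentricity: float = 0.60
    lymphocyte_area_ratio: float = 0.5   # of the epithelial median area
    min_nuclear_hem: float = 0.18    # below: non-nuclear (background) object
    strong_bg_dab: float = 0.45      # DAB OD separating strong from weak bg
    fold_dab_od: float = 0.70        # fold bands stain intensely in BOTH
    fold_hem_od: float = 0.65        # channels, unlike positive nuclei
    fold_min_area: int = 250         # px^2 for a fold-band component


def call_cells(rendered, params: CallParams | None = None) -> tuple[pd.DataFrame, dict]:
    """Detect and classify objects in a rendered (or compatible) core image.

    Accepts a :class:`RenderedCore` or a bare RGB array.  Returns the
    per-object call table and the aggregated 7-class counts for the core.
    Fold bands (large components strongly stained in both channels) are
    counted as strong background and masked out of nucleus detection.
    """
    params = params or CallParams()
    rgb = rendered.rgb if isinstance(rendered, RenderedCore) else np.asarray(rendered)
    od = deconvolve_stains(rgb)
    od_h, od_d = od[..., 0], od[..., 1]

    counts = {c: 0 for c in CLASS_COLUMNS}

    # fold/large-debris bands: intense in both stains, large area
    fold_px = (od_d > params.fold_dab_od) & (od_h > params.fold_hem_od)
    fold_labels = cc_label(fold_px)
    fold_mask = np.zeros_like(fold_px)
    for r in regionprops(fold_labels):
        if r.area >= params.fold_min_area:
            fold_mask[fold_labels == r.label] = True
            counts["strong_background"] += 1

    signal = ndimage.gaussian_filter(od_h + od_d, params.smooth_sigma)
    binary = (signal > params.detect_threshold) & ~fold_mask
    binary = ndimage.binary_opening(binary)

    distance = ndimage.distance_transform_edt(binary)
    comp = cc_label(binary)
    comp_areas = np.bincount(comp.ravel())
    large = comp_areas[comp] >= params.split_min_area
    peaks = peak_local_max(
        distance, min_distance=params.watershed_min_distance,
        labels=comp * large, exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # components too small to be touching nuclei keep a single label each,
    # as do large components that received no marker
    has_marker = set(np.unique(comp[markers > 0]))
    next_id = len(peaks) + 1
    for cid in range(1, len(comp_areas)):
        if comp_areas[cid] and cid not in has_marker:
            ys, xs = np.nonzero(comp == cid)
            markers[ys[len(ys) // 2], xs[len(ys) // 2]] = next_id
            next_id += 1
    labels = watershed(-distance, markers, mask=binary)

    rows = []
    regions = regionprops(labels)
    feats = []
    for r in regions:
        coords = tuple(r.coords.T)
        feats.append(
            (r.label, r.area, r.eccentricity, r.centroid,
             float(od_d[coords].mean()), float(od_h[coords].mean()))
        )
    feats = [f for f in feats if f[1] >= params.min_area]

    # adaptive epithelial reference area for the lymphocyte size rule
    round_large = [a for (_, a, ecc, _, _, _) in feats
                   if ecc < params.stromal_eccentricity and a >= 40]
    median_epi_area = float(np.median(round_large)) if round_large else 80.0

    for lbl, area, ecc, (cy, cx), mean_d, mean_h in feats:
        positive = mean_d >= params.positivity_cutoff
        if mean_h < params.min_nuclear_hem:
            cls = "strong_background" if mean_d >= params.strong_bg_dab else "weak_background"
            positive = None
        elif ecc >= params.stromal_eccentricity or (
            ecc >= params.lymphocyte_eccentricity and area < 0.55 * median_epi_area
        ):
            # clearly elongated, or a small eccentric fragment (a stromal
            # nucleus clipped by the watershed at a cell cluster boundary)
            cls = "positive_stromal" if positive else "negative_stromal"
        elif (area < params.lymphocyte_area_ratio * median_epi_area
              and ecc < params.lymphocyte_eccentricity):
            cls = "lymphocyte"
            positive = None
        else:
            cls = "positive_tumor" if positive else "negative_tumor"
        counts[cls] += 1
        rows.append({"label": lbl, "y": cy, "x": cx, "area": int(area),
                     "eccentricity": float(ecc), "mean_dab_od": mean_d,
                     "mean_hematoxylin_od": mean_h, "called_class": cls,
                     "positive": positive})
    calls = pd.DataFrame(rows, columns=["label", "y", "x", "area", "eccentricity",
                                        "mean_dab_od", "mean_hematoxylin_od",
                                        "called_class", "positive"])
    return calls, counts


# ---------------------------------------------------------------------------
# spec builders


def make_core_spec(
    n_epithelial: int = 200,
    frac_positive_epithelial: float = 0.9,
    n_stromal: int = 110,
    frac_positive_stromal: float = 0.85,
    n_lymphocytes: int = 30,
    frac_positive_lymphocytes: float = 0.9,
    n_strong_debris: int = 2,
    n_weak_blobs: int = 3,
    fold: bool = False,
    diameter: int = 360,
    seed: int = 0,
) -> CoreImageSpec:
    """Lay out a plausible core: epithelial nuclei in glandular clusters,
    small round lymphocytes, elongated stromal nuclei, plus artifacts."""
    rng = np.random.default_rng(seed)
    spec = CoreImageSpec(diameter=diameter, seed=seed)
    center = spec.size / 2.0
    radius = diameter / 2.0 - 6.0

    placed: list[tuple[float, float]] = []

    def place(max_r, min_sep, anchor=None, spread=None, tries=60):
        for _ in range(tries):
            if anchor is None:
                rr = max_r * math.sqrt(rng.random())
                ang = rng.random() * 2 * math.pi
                y, x = center + rr * math.sin(ang), center + rr * math.cos(ang)
            else:
                y = anchor[0] + rng.normal(0, spread)
                x = anchor[1] + rng.normal(0, spread)
                if (y - center) ** 2 + (x - center) ** 2 > max_r * max_r:
                    continue
            if placed:
                arr = np.asarray(placed)
                if np.min((arr[:, 0] - y) ** 2 + (arr[:, 1] - x) ** 2) < min_sep * min_sep:
                    continue
            placed.append((y, x))
            return y, x
        return None

    def dab(positive):
        return float(np.clip(rng.normal(0.65, 0.08), 0.4, 0.95)) if positive \
            else float(rng.uniform(0.0, 0.04))

    n_clusters = max(1, n_epithelial // 45)
    clusters = [place(0.70 * radius, 30.0) or (center, center) for _ in range(n_clusters)]
    # cluster centers are anchors, not nuclei
    placed = []

    for _ in range(n_epithelial):
        anchor = clusters[rng.integers(len(clusters))]
        pos = place(radius - 8, 9.5, anchor=anchor, spread=26.0)
        if pos is None:
            pos = place(radius - 8, 9.5)
        if pos is None:
            continue
        positive = rng.random() < frac_positive_epithelial
        spec.nuclei.append(Nucleus(
            pos[0], pos[1],
            ry=float(rng.uniform(4.0, 5.0)), rx=float(rng.uniform(5.2, 6.5)),
            theta=float(rng.uniform(0, math.pi)),
            cls="positive_tumor" if positive else "negative_tumor",
            dab_od=dab(positive), hem_od=float(rng.normal(0.55, 0.04)),
        ))

    for _ in range(n_stromal):
        pos = place(radius - 10, 15.0)
        if pos is None:
            continue
        positive = rng.random() < frac_positive_stromal
        spec.nuclei.append(Nucleus(
            pos[0], pos[1],
            ry=float(rng.uniform(1.5, 1.9)), rx=float(rng.uniform(8.5, 10.5)),
            theta=float(rng.uniform(0, math.pi)),
            cls="positive_stromal" if positive else "negative_stromal",
            dab_od=dab(positive), hem_od=float(rng.normal(0.55, 0.04)),
        ))

    for _ in range(n_lymphocytes):
        pos = place(radius - 8, 8.0)
        if pos is None:
            continue
        r = float(rng.uniform(2.3, 3.0))
        positive = rng.random() < frac_positive_lymphocytes
        spec.nuclei.append(Nucleus(
            pos[0], pos[1], ry=r, rx=r * float(rng.uniform(1.0, 1.1)),
            theta=0.0, cls="lymphocyte",
            dab_od=dab(positive), hem_od=float(rng.normal(0.9, 0.05)),
        ))

    for _ in range(n_strong_debris):
        pos = place(radius - 8, 12.0)
        if pos is None:
            continue
        spec.nuclei.append(Nucleus(
            pos[0], pos[1], ry=float(rng.uniform(3.0, 4.5)), rx=float(rng.uniform(3.5, 5.5)),
            theta=float(rng.uniform(0, math.pi)), cls="strong_background",
            dab_od=float(rng.uniform(0.7, 0.9)), hem_od=float(rng.uniform(0.0, 0.08)),
        ))

    for _ in range(n_weak_blobs):
        pos = place(radius - 12, 16.0)
        if pos is None:
            continue
        spec.nuclei.append(Nucleus(
            pos[0], pos[1], ry=float(rng.uniform(5.0, 7.0)), rx=float(rng.uniform(6.0, 9.0)),
            theta=float(rng.uniform(0, math.pi)), cls="weak_background",
            dab_od=float(rng.uniform(0.26, 0.34)), hem_od=float(rng.uniform(0.0, 0.04)),
        ))

    if fold:
        spec.fold_bands.append(
            (float(rng.uniform(0, math.pi)), float(rng.uniform(-0.3, 0.3) * radius),
             float(rng.uniform(0.10, 0.16) * diameter))
        )
    return spec


def match_calls_to_truth(calls: pd.DataFrame, rendered: RenderedCore) -> pd.DataFrame:
    """Join called objects to rendered ground truth via the label mask at the
    call centroid (NaN truth class where the centroid lands on background)."""
    ids = []
    for rec in calls.itertuples(index=False):
        yy = int(round(rec.y))
        xx = int(round(rec.x))
        yy = min(max(yy, 0), rendered.mask.shape[0] - 1)
        xx = min(max(xx, 0), rendered.mask.shape[1] - 1)
        ids.append(int(rendered.mask[yy, xx]))
    out = calls.copy()
    out["nucleus_id"] = ids
    truth = rendered.truth.rename(columns={"cls": "true_class", "positive": "true_positive"})
    return out.merge(truth[["nucleus_id", "true_class", "true_positive"]],
                     on="nucleus_id", how="left")


def counts_to_row(case_id: str, core_id: str, region: str, protein: str,
                  counts: dict, stain_fail_flag: bool = False) -> dict:
    row = {"case_id": case_id, "core_id": core_id, "region": region, "protein": protein}
    row.update({c: int(counts.get(c, 0)) for c in CLASS_COLUMNS})
    row["stain_fail_flag"] = stain_fail_flag
    return row


def render_cohort_tables(
    truth: pd.DataFrame,
    n_cores: int = 2,
    n_epithelial: int = 200,
    n_stromal: int = 110,
    n_lymphocytes: int = 30,
    params: CallParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render every core section for the given case truth table, run the cell
    caller, and return (called_counts, truth_counts) cell-count tables.

    Truth counts come from the rendered ground truth; called counts from
    :func:`call_cells`.  Intended for end-to-end image -> call -> score
    validation on small cohorts.
    """
    from .cohort import PROTEINS

    called_rows, truth_rows = [], []
    for ci, rec in enumerate(truth.itertuples(index=False)):
        for j in range(n_cores):
            region = "TC" if j < (n_cores + 1) // 2 else "IM"
            core_id = f"{rec.case_id}_core{j}"
            for pi, protein in enumerate(PROTEINS):
                spec = make_core_spec(
                    n_epithelial=n_epithelial,
                    frac_positive_epithelial=getattr(rec, f"latent_epi_{protein}"),
                    n_stromal=n_stromal,
                    frac_positive_stromal=getattr(rec, f"latent_str_{protein}"),
                    n_lymphocytes=n_lymphocytes,
                    seed=seed + 10007 * ci + 101 * j + pi,
                )
                rendered = render_core(spec)
                _, counts = call_cells(rendered, params)
                called_rows.append(counts_to_row(rec.case_id, core_id, region, protein, counts))
                tc = {c: 0 for c in CLASS_COLUMNS}
                for t in rendered.truth.itertuples(index=False):
                    tc[t.cls] += 1
                truth_rows.append(counts_to_row(rec.case_id, core_id, region, protein, tc))
    return pd.DataFrame(called_rows), pd.DataFrame(truth_rows)
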