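"""Synthetic abdominal fat–water MRI phantoms with known ground truth.

Each phantom is an elliptical body containing a bright subcutaneous fat (SAT)
annulus just inside the body border, a set of visceral fat (VAT) blobs, and
two dark kidneys (a visual anchor for the kidney-window concept, with no
computational role). Two intensity regimes are modelled after the protocols
the pipeline targets:

* mouse: T1 RARE base + CHESS fat-suppressed water images, fat signal around
  30,000, high additive background noise; the fat image is base − water;
* human: 2-point Dixon in-phase/out-of-phase pairs, all intensities below
  500, nearly clean background; the fat image comes from the Dixon
  sum/difference combination.

The SAT annulus has angular gaps (fat coverage ≈ 70 % of the perimeter), as
real subcutaneous rings are lobular and interrupted; this also means the body
contour samples both fat and non-fat voxels, which is what makes the
contour-statistics threshold meaningful. Background voxels carry folded
Gaussian noise (magnitude images are non-negative). Everything is
deterministic for a fixed seed.

When ``sat_vat_gap`` is 0 one VAT blob is placed in contact with the SAT
annulus, and a suggested 1-voxel-wide cut line (the SAT voxels 4-adjacent to
VAT) is emitted so the edit-script splitting/reinsertion path can be
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image_io import (
    HUMAN_GEOMETRY,
    MOUSE_GEOMETRY,
    ImageStack,
    SubjectScan,
    VoxelGeometry,
    derive_fat_image,
    dixon_combine,
)
from .preprocess import compute_body_mask
from .segment import (
    SAT,
    VAT,
    EditScript,
    VolumeReport,
    label_objects,
    quantify_volumes,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "mouse_spec",
    "human_spec",
    "generate_phantom",
    "perturb_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    species: str
    width: int
    height: int
    n_slices: int
    geometry: VoxelGeometry
    body_a: float                   # body half-axis along columns (voxels)
    body_b: float                   # body half-axis along rows (voxels)
    sat_thickness: float            # annulus thickness (voxels)
    sat_gap_sectors: tuple[tuple[float, float], ...]  # degrees, fat absent
    sat_vat_gap: int                # min ring-to-blob distance; 0 = contact
    n_vat_blobs: int
    blob_radius_range: tuple[float, float]
    kidneys: tuple[tuple[float, float, float, float], ...]  # (dx, dy, a, b) offsets from centre
    tissue_intensity: float
    fat_intensity: float            # fat-image signal level of adipose voxels
    kidney_intensity: float
    background_noise_sd: float
    fat_suppression_residual: float  # CHESS leakage fraction (mouse scheme)
    slice_scale_amplitude: float = 0.03
    seed: int = 0

    def with_(self, **overrides) -> "PhantomSpec":
        return replace(self, **overrides)


def mouse_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset emulating the small-animal protocol: 256 x 256 voxels of
    0.156 x 0.156 x 1 mm, fat signal ~30,000, high background noise."""
    spec = PhantomSpec(
        species="mouse",
        width=256,
        height=256,
        n_slices=10,
        geometry=MOUSE_GEOMETRY,
        body_a=88.0,
        body_b=68.0,
        sat_thickness=8.0,
        sat_gap_sectors=((40.0, 95.0), (220.0, 275.0)),
        sat_vat_gap=3,
        n_vat_blobs=3,
        blob_radius_range=(4.0, 6.0),
        kidneys=((-30.0, 0.0, 10.0, 16.0), (30.0, 0.0, 10.0, 16.0)),
        tissue_intensity=20000.0,
        fat_intensity=30000.0,
        kidney_intensity=8000.0,
        background_noise_sd=1500.0,
        fat_suppression_residual=0.05,
        seed=seed,
    )
    return spec.with_(**overrides) if overrides else spec


def human_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Preset emulating the clinical 2-point Dixon protocol: 320 x 240 voxels
    of 1.234 x 1.234 x 2.5 mm, all intensities below 500, clean background."""
    spec = PhantomSpec(
        species="human",
        width=320,
        height=240,
        n_slices=10,
        geometry=HUMAN_GEOMETRY,
        body_a=140.0,
        body_b=95.0,
        sat_thickness=14.0,
        sat_gap_sectors=((40.0, 95.0), (220.0, 275.0)),
        sat_vat_gap=4,
        n_vat_blobs=3,
        blob_radius_range=(8.0, 12.0),
        kidneys=((-48.0, 0.0, 16.0, 24.0), (48.0, 0.0, 16.0, 24.0)),
        tissue_intensity=150.0,
        fat_intensity=180.0,
        kidney_intensity=60.0,
        background_noise_sd=2.0,
        fat_suppression_residual=0.0,
        seed=seed,
    )
    return spec.with_(**overrides) if overrides else spec


@dataclass
class PhantomTruth:
    """Ground truth bundled with a generated phantom."""

    depot_map: np.ndarray          # (n_slices, h, w) uint8, 0/1/2
    body_mask: np.ndarray          # (n_slices, h, w) bool
    report: VolumeReport
    edits: EditScript              # suggested depot seeds (and cut lines at gap 0)
    spec: PhantomSpec = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def sat_voxels(self) -> int:
        return self.report.sat_voxels

    @property
    def vat_voxels(self) -> int:
        return self.report.vat_voxels


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse(h: int, w: int, cy: float, cx: float, b: float, a: float) -> np.ndarray:
    """Voxel-centre-in-ellipse mask; half-axes a (cols) and b (rows)."""
    if a <= 0 or b <= 0:
        return np.zeros((h, w), dtype=bool)
    rows = (np.arange(h) - cy)[:, None] / b
    cols = (np.arange(w) - cx)[None, :] / a
    return rows**2 + cols**2 <= 1.0


def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    return _ellipse(h, w, cy, cx, r, r)


def _angles(h: int, w: int, cy: float, cx: float) -> np.ndarray:
    rows = (np.arange(h) - cy)[:, None]
    cols = (np.arange(w) - cx)[None, :]
    return np.degrees(np.arctan2(rows, cols)) % 360.0


_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _validate(spec: PhantomSpec) -> None:
    if spec.n_slices < 1:
        raise ValueError("spec infeasible: need at least one slice")
    amp = spec.slice_scale_amplitude
    if spec.body_a * (1 + amp) + 2 >= spec.width / 2 or spec.body_b * (1 + amp) + 2 >= spec.height / 2:
        raise ValueError("spec infeasible: body does not fit inside the image")
    if spec.sat_thickness >= min(spec.body_a, spec.body_b) * (1 - amp):
        raise ValueError("spec infeasible: annulus thicker than the body")
    cy, cx = spec.height / 2, spec.width / 2
    inner_a = spec.body_a * (1 - amp) - spec.sat_thickness
    inner_b = spec.body_b * (1 - amp) - spec.sat_thickness
    for dx, dy, ka, kb in spec.kidneys:
        if ((dx + np.sign(dx) * ka) / inner_a) ** 2 + ((dy + np.sign(dy) * kb) / inner_b) ** 2 >= 1:
            raise ValueError("spec infeasible: kidney outside the visceral cavity")
    if spec.n_vat_blobs > 0:
        rmax = spec.blob_radius_range[1]
        if min(inner_a, inner_b) - spec.sat_vat_gap - rmax - 2 <= 0:
            raise ValueError("spec infeasible: no room for visceral blobs")
    if not (0 <= spec.fat_suppression_residual < 1):
        raise ValueError("spec infeasible: suppression residual must be in [0, 1)")


def _place_blobs(spec: PhantomSpec, rng: np.random.Generator):
    """Blob (cx, cy, r) triples valid on every slice; seeded rejection sampling.

    When ``sat_vat_gap`` is 0 the first blob is returned separately as the
    contact blob (placed per slice against the annulus).
    """
    cy0, cx0 = spec.height / 2, spec.width / 2
    fmin = 1 - spec.slice_scale_amplitude
    inner_a = spec.body_a * fmin - spec.sat_thickness
    inner_b = spec.body_b * fmin - spec.sat_thickness
    contact_r = None
    n_free = spec.n_vat_blobs
    if spec.sat_vat_gap == 0 and spec.n_vat_blobs > 0:
        # thin contact neck: a fat window covering both the annulus and a
        # large touching blob would locally exceed the threshold margin
        contact_r = 0.75 * float(spec.blob_radius_range[0])
        n_free -= 1
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_free):
        for _attempt in range(400):
            r = float(rng.uniform(*spec.blob_radius_range))
            margin_a = inner_a - max(spec.sat_vat_gap, 1) - r - 2
            margin_b = inner_b - max(spec.sat_vat_gap, 1) - r - 2
            if margin_a <= 0 or margin_b <= 0:
                raise ValueError("spec infeasible: no room for visceral blobs")
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v > 1:
                continue
            bx, by = cx0 + u * margin_a, cy0 + v * margin_b
            ok = True
            for dx, dy, ka, kb in spec.kidneys:
                if ((bx - (cx0 + dx)) / (ka + r + 2)) ** 2 + ((by - (cy0 + dy)) / (kb + r + 2)) ** 2 <= 1:
                    ok = False
                    break
            for ox, oy, orr in placed:
                if (bx - ox) ** 2 + (by - oy) ** 2 <= (r + orr + 3) ** 2:
                    ok = False
                    break
            if ok:
                placed.append((bx, by, r))
                break
        else:
            raise ValueError("spec infeasible: blob placement failed")
    return placed, contact_r


def _slice_masks(spec: PhantomSpec, s: int, blobs, contact_r):
    """Body / SAT / VAT / kidney masks of slice ``s``."""
    h, w = spec.height, spec.width
    cy, cx = h / 2, w / 2
    f = 1 + spec.slice_scale_amplitude * np.cos(2 * np.pi * s / max(spec.n_slices, 1))
    a, b = spec.body_a * f, spec.body_b * f
    body = _ellipse(h, w, cy, cx, b, a)
    inner = _ellipse(h, w, cy, cx, b - spec.sat_thickness, a - spec.sat_thickness)
    ring = body & ~inner
    theta = _angles(h, w, cy, cx)
    gap = np.zeros((h, w), dtype=bool)
    for lo, hi in spec.sat_gap_sectors:
        gap |= (theta >= lo) & (theta < hi)
    sat = ring & ~gap

    kidneys = np.zeros((h, w), dtype=bool)
    for dx, dy, ka, kb in spec.kidneys:
        kidneys |= _ellipse(h, w, cy + dy, cx + dx, kb, ka)

    vat = np.zeros((h, w), dtype=bool)
    for bx, by, r in blobs:
        vat |= _disk(h, w, by, bx, r)
    if contact_r is not None:
        # contact blob tucked against the annulus in the middle of a fat sector
        sectors = sorted(spec.sat_gap_sectors)
        theta0 = np.radians((sectors[0][1] + sectors[1][0]) / 2.0)
        ia, ib = a - spec.sat_thickness, b - spec.sat_thickness
        radial = np.hypot(ia * np.cos(theta0), ib * np.sin(theta0))
        u = max(1 - (contact_r - 0.5) / radial, 0.0)
        bx = cx + ia * np.cos(theta0) * u
        by = cy + ib * np.sin(theta0) * u
        vat |= _disk(h, w, by, bx, contact_r)
    vat &= inner & ~kidneys
    return body, sat, vat, kidneys


def _add_noise(signal: np.ndarray, body: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise in the body, folded Gaussian in the background."""
    noise = rng.standard_normal(signal.shape) * sd
    out = np.where(body, np.maximum(signal + noise, 0.0), np.abs(noise))
    return out


def _suggest_edits(depot_map: np.ndarray, spec: PhantomSpec) -> EditScript:
    """Truth-derived depot seeds (one per connected component per slice) and,
    at contact (gap 0), the separating cut line on the SAT side."""
    edits = EditScript()
    for s in range(depot_map.shape[0]):
        sl = depot_map[s]
        cuts: set[tuple[int, int]] = set()
        if spec.sat_vat_gap == 0:
            sat_mask = sl == SAT
            vat_neigh = ndimage.binary_dilation(sl == VAT, structure=_STRUCT_4)
            cuts = {tuple(v) for v in np.argwhere(sat_mask & vat_neigh)}
            edits.cut_voxels.extend((s, r, c) for r, c in sorted(cuts))
        cut_mask = np.zeros(sl.shape, dtype=bool)
        for r, c in cuts:
            cut_mask[r, c] = True
        for depot in (SAT, VAT):
            # seed every component as it will appear after the cuts are applied
            mask = (sl == depot) & ~cut_mask
            if not mask.any():
                continue
            labels = label_objects(mask.astype(np.uint8), connectivity=4)
            dist = ndimage.distance_transform_edt(mask)
            for k in range(1, int(labels.max()) + 1):
                d = np.where(labels == k, dist, -np.inf)
                r, c = np.unravel_index(int(np.argmax(d)), d.shape)
                edits.depot_seeds.append((s, int(r), int(c), depot))
    return edits


def generate_phantom(spec: PhantomSpec) -> tuple[SubjectScan, PhantomTruth]:
    """Generate a phantom scan and its ground truth; deterministic per seed."""
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    blobs, contact_r = _place_blobs(spec, rng)

    h, w, n = spec.height, spec.width, spec.n_slices
    depot_map = np.zeros((n, h, w), dtype=np.uint8)
    body_mask = np.zeros((n, h, w), dtype=bool)
    stack_a = np.zeros((n, h, w))  # base (mouse) or in-phase (human)
    stack_b = np.zeros((n, h, w))  # water (mouse) or out-of-phase (human)

    for s in range(n):
        body, sat, vat, kidneys = _slice_masks(spec, s, blobs, contact_r)
        fatvox = sat | vat
        depot_map[s][sat] = SAT
        depot_map[s][vat] = VAT
        body_mask[s] = body

        if spec.species == "mouse":
            base = np.where(body, spec.tissue_intensity, 0.0)
            base[kidneys] = spec.kidney_intensity
            base[fatvox] = spec.fat_intensity
            water = base.copy()
            water[fatvox] = spec.fat_intensity * spec.fat_suppression_residual
            stack_a[s] = _add_noise(base, body, spec.background_noise_sd, rng)
            stack_b[s] = _add_noise(water, body, spec.background_noise_sd, rng)
        else:
            # water content equals fat content at fat voxels so OP >= 0 and
            # the Dixon combination recovers the fat image exactly
            water = np.where(body, spec.tissue_intensity, 0.0)
            water[kidneys] = spec.kidney_intensity
            water[fatvox] = spec.fat_intensity
            fat = np.where(fatvox, spec.fat_intensity, 0.0)
            stack_a[s] = _add_noise(water + fat, body, spec.background_noise_sd, rng)
            stack_b[s] = _add_noise(water - fat, body, spec.background_noise_sd, rng)

    geometry = spec.geometry
    if spec.species == "mouse":
        base_stack = ImageStack(stack_a, geometry, "base")
        water_stack = ImageStack(stack_b, geometry, "water")
        fat_stack = derive_fat_image(base_stack, water_stack)
        scan = SubjectScan(
            subject_id=f"{spec.species}-{spec.seed}",
            species="mouse",
            fat=fat_stack,
            anatomy_reference=base_stack,
            water=water_stack,
        )
    else:
        ip_stack = ImageStack(stack_a, geometry, "in_phase")
        op_stack = ImageStack(stack_b, geometry, "out_phase")
        water_stack, fat_stack = dixon_combine(ip_stack, op_stack)
        scan = SubjectScan(
            subject_id=f"{spec.species}-{spec.seed}",
            species="human",
            fat=fat_stack,
            anatomy_reference=ip_stack,
            water=water_stack,
            out_phase=op_stack,
        )

    report = quantify_volumes(depot_map, geometry)
    truth = PhantomTruth(depot_map, body_mask, report, _suggest_edits(depot_map, spec), spec)
    return scan, truth


def perturb_phantom(
    scan: SubjectScan, kind: str, magnitude: float, seed: int = 0
) -> SubjectScan:
    """Add a named, reproducible artefact to a scan; the truth is unchanged.

    ``extra_background_noise`` adds folded Gaussian noise of the given sd
    outside the body (re-derived from the anatomy reference); fat suppression
    is known to degrade under field inhomogeneity, so ``suppression_artifact``
    plants ``int(magnitude)`` spurious bright voxels inside the body of every
    slice of the fat image — the kind of defect the scripted removal edits
    repair.
    """
    rng = np.random.default_rng(seed)
    fat = scan.fat.data.copy()
    if kind == "extra_background_noise":
        for s in range(fat.shape[0]):
            body = compute_body_mask(scan.anatomy_reference.data[s]).mask
            noise = np.abs(rng.standard_normal(fat[s].shape)) * magnitude
            fat[s] = np.where(body, fat[s], fat[s] + noise)
    elif kind == "suppression_artifact":
        k = int(magnitude)
        level = float(fat.max()) if fat.max() > 0 else 1.0
        for s in range(fat.shape[0]):
            body = compute_body_mask(scan.anatomy_reference.data[s]).mask
            candidates = np.argwhere(body & (fat[s] < 0.1 * level))
            if k > 0 and candidates.size:
                pick = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False)
                for r, c in candidates[pick]:
                    fat[s, r, c] = level
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    new_fat = ImageStack(fat, scan.fat.geometry, "fat", scan.fat.source_indices.copy())
    return SubjectScan(
        subject_id=scan.subject_id,
        species=scan.species,
        fat=new_fat,
        anatomy_reference=scan.anatomy_reference,
        water=scan.water,
        out_phase=scan.out_phase,
    )
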