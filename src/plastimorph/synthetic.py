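"""Seeded synthetic SEM micrographs with analytic ground truth.

Real weathered-plastic micrographs are not redistributable, so validation
rests on generated scenes whose geometry is known exactly: fibre meshes of
stated width and spacing, crack networks of known total centreline length,
disjoint perforation fields, periodic bump lattices, and bright spherical
nurdles — all under detector-style noise (additive Gaussian, optional
signal-dependent shot noise).

Every generator takes an explicit integer seed and uses its own
``numpy.random.Generator``; there is no global random state, and the same
seed reproduces the same image bit for bit.  Rasterization is hard-edged (no
anti-aliasing) so pixel-count oracles are exact: each primitive records both
its continuous analytic geometry and its exact rasterized pixel count.

These scenes emulate the geometry and first-order noise of SEM imagery, not
the physics: no charging artefacts, no detector shading, no beam-specimen
interaction models.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from shapely.geometry import LineString

from .calibration import CalibratedImage

__all__ = [
    "Primitive",
    "SyntheticGroundTruth",
    "add_sem_noise",
    "gen_fibre_mesh",
    "gen_crack_field",
    "gen_pore_field",
    "gen_texture",
    "gen_spheres",
]

SCHEMA_VERSION = 1

# default luminance levels, chosen for SEM-like mid-grey substrates with
# bright raised features and dark recesses
BG_GREY = 150
FIBRE_GREY = 220
CRACK_GREY = 40
PORE_GREY = 30
SPHERE_GREY = 210

DEFAULT_NOISE_SIGMA = 8.0  # luminance levels; SNR ~ 10 against the defaults


@dataclass(frozen=True)
class Primitive:
    """One generated feature and its analytic geometry."""

    kind: str  # fibre | disk | crack_segment | pore | texture_bump
    params: dict
    analytic_length_um: float | None = None
    analytic_area_um2: float | None = None
    rasterized_px: int | None = None


@dataclass
class SyntheticGroundTruth:
    primitives: list[Primitive]
    image_size_px: tuple[int, int]
    pixel_size_nm: float
    noise: dict
    seed: int
    flags: dict = field(default_factory=dict)

    @property
    def total_length_um(self) -> float:
        return sum(p.analytic_length_um or 0.0 for p in self.primitives)

    @property
    def total_area_um2(self) -> float:
        return sum(p.analytic_area_um2 or 0.0 for p in self.primitives)

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "image_size_px": list(self.image_size_px),
            "pixel_size_nm": self.pixel_size_nm,
            "noise": self.noise,
            "seed": self.seed,
            "flags": self.flags,
            "primitives": [asdict(p) for p in self.primitives],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def add_sem_noise(
    pixels: np.ndarray,
    gaussian_sigma: float = DEFAULT_NOISE_SIGMA,
    shot: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Detector-style noise: optional shot noise, then additive Gaussian.

    Shot noise is signal-dependent: luminance is treated as ``gain``
    electrons per level, Poisson-resampled, and rescaled.  With
    ``gaussian_sigma=0`` and ``shot=False`` the input is returned unchanged
    (bit-identical copy).
    """
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be non-negative")
    out = np.asarray(pixels, dtype=np.float64)
    if gaussian_sigma == 0 and not shot:
        return np.asarray(pixels, dtype=np.uint8).copy()
    rng = np.random.default_rng(seed)
    if shot:
        gain = 4.0
        out = rng.poisson(out / gain) * gain
    if gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _capsule_mask(shape: tuple[int, int], p0, p1, half_width_px: float) -> np.ndarray:
    """Hard-rasterized thick segment: pixels within half_width of the segment."""
    rr, cc = np.indices(shape, dtype=np.float64)
    r0, c0 = p0
    r1, c1 = p1
    dr, dc = r1 - r0, c1 - c0
    seg2 = dr * dr + dc * dc
    if seg2 == 0:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    else:
        t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / seg2, 0.0, 1.0)
        d2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
    return d2 <= half_width_px * half_width_px


def _disk_mask(shape: tuple[int, int], centre, radius_px: float) -> np.ndarray:
    rr, cc = np.indices(shape, dtype=np.float64)
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius_px * radius_px


# ---------------------------------------------------------------------------
# fibre meshes (glass fibre filter emulation)

def gen_fibre_mesh(
    n_fibres: int,
    widths_um: list[float],
    size_px: int = 512,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
    spacing_target_um: float | None = None,
    orientation_deg: float | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Bright fibres of the listed widths on a dark background.

    Widths are cycled over the fibres.  With ``spacing_target_um`` the fibres
    form a parallel array whose surface-to-surface gaps equal the target
    exactly (a calibration layout for gap-width estimators); otherwise each
    fibre is an independently random chord of the field.  If a parallel array
    of the requested count cannot fit the field, as many fibres as fit are
    drawn and the ground truth is flagged ``infeasible_packing``.
    """
    if any(w <= 0 for w in widths_um):
        raise ValueError("fibre widths must be positive")
    if spacing_target_um is not None and spacing_target_um <= 0:
        raise ValueError("spacing target must be positive")
    rng = np.random.default_rng(seed)
    p_um = pixel_size_nm / 1000.0
    img = np.full((size_px, size_px), BG_GREY - 90, dtype=np.float64)  # dark background
    prims: list[Primitive] = []
    flags: dict = {}
    diag = size_px * math.sqrt(2.0)

    if n_fibres > 0 and spacing_target_um is not None:
        theta = math.radians(orientation_deg if orientation_deg is not None else rng.uniform(0, 180))
        u = np.array([math.cos(theta), math.sin(theta)])      # along-fibre
        nvec = np.array([-math.sin(theta), math.cos(theta)])  # across-fibre
        widths_px = [widths_um[i % len(widths_um)] / p_um for i in range(n_fibres)]
        gap_px = spacing_target_um / p_um
        # centre offsets so consecutive surfaces are gap_px apart
        offsets = [0.0]
        for i in range(1, n_fibres):
            offsets.append(offsets[-1] + widths_px[i - 1] / 2 + gap_px + widths_px[i] / 2)
        total_extent = offsets[-1] + widths_px[0] / 2 + widths_px[-1] / 2
        if total_extent > diag:
            warnings.warn("requested parallel fibre array exceeds the field; truncating")
            flags["infeasible_packing"] = True
        centre = np.array([size_px / 2, size_px / 2])
        start = centre - nvec * (offsets[-1] / 2)
        for i, (w_px, off) in enumerate(zip(widths_px, offsets)):
            c = start + nvec * off
            p0 = c - u * diag
            p1 = c + u * diag
            mask = _capsule_mask(img.shape, tuple(p0), tuple(p1), w_px / 2)
            if not mask.any():
                continue
            img[mask] = FIBRE_GREY
            prims.append(
                Primitive(
                    kind="fibre",
                    params={
                        "width_um": w_px * p_um,
                        "orientation_deg": math.degrees(theta),
                        "centre_offset_px": off,
                        "gap_to_next_um": spacing_target_um if i < n_fibres - 1 else None,
                    },
                    rasterized_px=int(mask.sum()),
                )
            )
    else:
        for i in range(n_fibres):
            w_px = widths_um[i % len(widths_um)] / p_um
            theta = rng.uniform(0, math.pi)
            u = np.array([math.cos(theta), math.sin(theta)])
            c = rng.uniform(0.2 * size_px, 0.8 * size_px, size=2)
            p0, p1 = c - u * diag, c + u * diag
            mask = _capsule_mask(img.shape, tuple(p0), tuple(p1), w_px / 2)
            img[mask] = FIBRE_GREY
            prims.append(
                Primitive(
                    kind="fibre",
                    params={"width_um": w_px * p_um, "orientation_deg": math.degrees(theta)},
                    rasterized_px=int(mask.sum()),
                )
            )

    noisy = add_sem_noise(np.clip(img, 0, 255).astype(np.uint8), noise_sigma, seed=seed + 1)
    gt = SyntheticGroundTruth(
        primitives=prims,
        image_size_px=(size_px, size_px),
        pixel_size_nm=pixel_size_nm,
        noise={"gaussian_sigma": noise_sigma, "shot": False},
        seed=seed,
        flags=flags,
    )
    return CalibratedImage(noisy, pixel_size_nm), gt


# ---------------------------------------------------------------------------
# crack networks (weathered ghost nets / foil surfaces)

def gen_crack_field(
    total_length_um: float,
    n_segments: int,
    size_px: int = 512,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
    line_width_px: float = 2.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    margin_px: float = 6.0,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Dark, mutually disjoint crack segments on a mid-grey substrate.

    The requested total length is split randomly over the segments; each
    segment's endpoints are snapped to the pixel grid and its *exact*
    centreline length is recorded, so the stored lengths sum to the request
    within the endpoint-rounding bound.  Segments are rejection-sampled to
    stay ``margin_px`` apart (junction-free networks keep the centreline
    length analytically meaningful); if placement fails the field is flagged
    ``infeasible_packing`` and drawn best-effort.
    """
    if total_length_um < 0:
        raise ValueError("total_length_um must be non-negative")
    rng = np.random.default_rng(seed)
    p_um = pixel_size_nm / 1000.0
    img = np.full((size_px, size_px), BG_GREY, dtype=np.uint8)
    prims: list[Primitive] = []
    flags: dict = {}

    if total_length_um > 0 and n_segments > 0:
        fracs = rng.dirichlet(np.full(n_segments, 4.0))
        lengths_px = fracs * (total_length_um / p_um)
        max_len = size_px - 2 * margin_px - 2
        lengths_px = np.clip(lengths_px, 4.0, max_len)
        lengths_px *= (total_length_um / p_um) / lengths_px.sum()
        lengths_px = np.clip(lengths_px, 4.0, max_len)

        placed: list[LineString] = []
        crack_mask = np.zeros(img.shape, dtype=bool)
        clearance = line_width_px / 2 + margin_px / 2
        for l_px in lengths_px:
            ok = False
            for _ in range(500):
                theta = rng.uniform(0, math.pi)
                dr, dc = l_px * math.sin(theta), l_px * math.cos(theta)
                # both endpoints must stay inside the margin frame
                r0 = rng.uniform(margin_px + max(0.0, -dr), size_px - margin_px - max(0.0, dr))
                c0 = rng.uniform(margin_px + max(0.0, -dc), size_px - margin_px - max(0.0, dc))
                a = (round(r0), round(c0))
                b = (round(r0 + dr), round(c0 + dc))
                if a == b:
                    continue
                cand = LineString([a, b]).buffer(clearance)
                if any(cand.intersects(q) for q in placed):
                    continue
                ok = True
                break
            if not ok:
                flags["infeasible_packing"] = True
                warnings.warn("crack placement infeasible; drawing best effort")
            placed.append(LineString([a, b]).buffer(clearance))
            mask = _capsule_mask(img.shape, a, b, line_width_px / 2)
            crack_mask |= mask
            seg_len_um = math.hypot(b[0] - a[0], b[1] - a[1]) * p_um
            prims.append(
                Primitive(
                    kind="crack_segment",
                    params={"r0": a[0], "c0": a[1], "r1": b[0], "c1": b[1]},
                    analytic_length_um=seg_len_um,
                    rasterized_px=int(mask.sum()),
                )
            )
        img[crack_mask] = CRACK_GREY

    noisy = add_sem_noise(img, noise_sigma, seed=seed + 1)
    gt = SyntheticGroundTruth(
        primitives=prims,
        image_size_px=(size_px, size_px),
        pixel_size_nm=pixel_size_nm,
        noise={"gaussian_sigma": noise_sigma, "shot": False},
        seed=seed,
        flags=flags,
    )
    return CalibratedImage(noisy, pixel_size_nm), gt


# ---------------------------------------------------------------------------
# perforation fields

def gen_pore_field(
    n_pores: int,
    pore_area_um2: float,
    size_px: int = 512,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    margin_px: float = 2.0,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Disjoint dark circular pores of equal nominal area on mid-grey.

    Pores are rejection-sampled to keep at least ``margin_px`` of substrate
    between rims and to stay inside the field.  Requests whose total pore
    area exceeds half the field are refused before drawing.
    """
    if n_pores < 0:
        raise ValueError("n_pores must be non-negative")
    if n_pores > 0 and pore_area_um2 <= 0:
        raise ValueError("pore_area_um2 must be positive")
    p_um = pixel_size_nm / 1000.0
    field_area = (size_px * p_um) ** 2
    if n_pores * pore_area_um2 >= 0.5 * field_area:
        raise ValueError(
            f"total pore area {n_pores * pore_area_um2:.3g} um^2 exceeds half "
            f"the field ({field_area:.3g} um^2); packing infeasible"
        )
    rng = np.random.default_rng(seed)
    img = np.full((size_px, size_px), BG_GREY, dtype=np.uint8)
    prims: list[Primitive] = []
    r_px = math.sqrt(pore_area_um2 / math.pi) / p_um
    centres: list[tuple[float, float]] = []
    # +1 px: hard rasterization reaches up to half a pixel beyond the
    # continuous radius on each side; the margin applies to the drawn rims
    min_gap = 2 * r_px + margin_px + 1.0
    for _ in range(n_pores):
        for attempt in range(2000):
            cr = rng.uniform(r_px + 1, size_px - r_px - 1)
            cc = rng.uniform(r_px + 1, size_px - r_px - 1)
            if all(math.hypot(cr - a, cc - b) >= min_gap for a, b in centres):
                break
        else:
            raise RuntimeError("pore rejection sampling failed; field too crowded")
        centres.append((cr, cc))
        mask = _disk_mask(img.shape, (cr, cc), r_px)
        img[mask] = PORE_GREY
        prims.append(
            Primitive(
                kind="pore",
                params={"centre_row": cr, "centre_col": cc, "radius_px": r_px},
                analytic_area_um2=math.pi * (r_px * p_um) ** 2,
                rasterized_px=int(mask.sum()),
            )
        )
    noisy = add_sem_noise(img, noise_sigma, seed=seed + 1)
    gt = SyntheticGroundTruth(
        primitives=prims,
        image_size_px=(size_px, size_px),
        pixel_size_nm=pixel_size_nm,
        noise={"gaussian_sigma": noise_sigma, "shot": False},
        seed=seed,
    )
    return CalibratedImage(noisy, pixel_size_nm), gt


# ---------------------------------------------------------------------------
# periodic textures

def gen_texture(
    period_px: tuple[int, int] = (20, 17),
    bump_shape: str = "gauss",
    size_px: int = 256,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    bump_size_px: float | None = None,
    amplitude: int = 120,
    phase: tuple[int, int] | None = None,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Exactly periodic bump lattice with periods ``(rows, cols)``.

    The lattice is constructed in modular coordinates, so the image is
    periodic to the pixel regardless of whether the field is a whole number
    of cells.  ``bump_shape`` is ``"gauss"`` (smooth bumps) or ``"disk"``
    (hard-edged, diameter ``bump_size_px``).
    """
    pr, pc = int(period_px[0]), int(period_px[1])
    if pr < 2 or pc < 2:
        raise ValueError("periods must be at least 2 px")
    if bump_shape not in ("gauss", "disk"):
        raise ValueError(f"unknown bump shape {bump_shape!r}")
    rng = np.random.default_rng(seed)
    if phase is None:
        phase = (int(rng.integers(0, pr)), int(rng.integers(0, pc)))
    rr, cc = np.indices((size_px, size_px), dtype=np.float64)
    dr = ((rr - phase[0] + pr / 2) % pr) - pr / 2
    dc = ((cc - phase[1] + pc / 2) % pc) - pc / 2
    d2 = dr * dr + dc * dc
    base = float(BG_GREY - 90)
    if bump_shape == "gauss":
        s = bump_size_px if bump_size_px is not None else min(pr, pc) / 6.0
        img = base + amplitude * np.exp(-d2 / (2 * s * s))
        extent_px = 2 * s * math.sqrt(2 * math.log(amplitude / 1.0))  # where bump ~ 1 level
    else:
        radius = (bump_size_px if bump_size_px is not None else min(pr, pc) / 2.5) / 2.0
        img = base + amplitude * (d2 <= radius * radius)
        extent_px = 2 * radius
    img_u8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    noisy = add_sem_noise(img_u8, noise_sigma, seed=seed + 1)
    p_um = pixel_size_nm / 1000.0
    prims = [
        Primitive(
            kind="texture_bump",
            params={
                "period_rows_px": pr,
                "period_cols_px": pc,
                "phase": list(phase),
                "bump_shape": bump_shape,
                "extent_px": extent_px,
                "period_rows_um": pr * p_um,
                "period_cols_um": pc * p_um,
            },
        )
    ]
    gt = SyntheticGroundTruth(
        primitives=prims,
        image_size_px=(size_px, size_px),
        pixel_size_nm=pixel_size_nm,
        noise={"gaussian_sigma": noise_sigma, "shot": False},
        seed=seed,
    )
    return CalibratedImage(noisy, pixel_size_nm), gt


# ---------------------------------------------------------------------------
# spherical nurdles

def gen_spheres(
    n: int,
    radius_um: tuple[float, float],
    size_px: int = 1024,
    pixel_size_nm: float = 200.0,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    margin_px: float = 4.0,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Disjoint bright disks (projected nurdles) with radii uniform in a range.

    Each primitive records the continuous radius, the analytic projected
    area πr², the closed-form sphere volume (4/3)πr³, and the exact
    rasterized pixel count.
    """
    lo, hi = radius_um
    if not (0 < lo <= hi):
        raise ValueError("radius range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    p_um = pixel_size_nm / 1000.0
    img = np.full((size_px, size_px), BG_GREY - 110, dtype=np.uint8)  # dark filter bed
    prims: list[Primitive] = []
    placed: list[tuple[float, float, float]] = []
    for _ in range(n):
        r_um = float(rng.uniform(lo, hi))
        r_px = r_um / p_um
        if 2 * r_px + 2 > size_px:
            raise ValueError("sphere larger than the field")
        for attempt in range(4000):
            cr = rng.uniform(r_px + 1, size_px - r_px - 1)
            cc = rng.uniform(r_px + 1, size_px - r_px - 1)
            if all(
                math.hypot(cr - a, cc - b) >= r_px + q + margin_px for a, b, q in placed
            ):
                break
        else:
            raise RuntimeError("sphere rejection sampling failed; field too crowded")
        placed.append((cr, cc, r_px))
        mask = _disk_mask(img.shape, (cr, cc), r_px)
        img[mask] = SPHERE_GREY
        prims.append(
            Primitive(
                kind="disk",
                params={
                    "centre_row": cr,
                    "centre_col": cc,
                    "radius_um": r_um,
                    "volume_um3": (4.0 / 3.0) * math.pi * r_um**3,
                },
                analytic_area_um2=math.pi * r_um * r_um,
                rasterized_px=int(mask.sum()),
            )
        )
    noisy = add_sem_noise(img, noise_sigma, seed=seed + 1)
    gt = SyntheticGroundTruth(
        primitives=prims,
        image_size_px=(size_px, size_px),
        pixel_size_nm=pixel_size_nm,
        noise={"gaussian_sigma": noise_sigma, "shot": False},
        seed=seed,
    )
    return CalibratedImage(noisy, pixel_size_nm), gt
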