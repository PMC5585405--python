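"""Seeded synthetic single-slice CT phantoms with ground-truth labels.

The phantoms emulate the anatomy the segmentation pipelines assume —
a body outline above a patient table, a SAT ring, an abdominal muscle
wall enclosing a cavity with visceral fat, organs and paraspinal
structures; a liver/spleen slice with adjustable liver attenuation; and
two thighs with cortical bone and marrow, muscle, SAT, a thin fascia
lata with a subfascial fat band, and intermuscular fat islands.  Every
tissue is drawn from its HU band with additive Gaussian noise; pixels
are deterministic given the spec (including its seed).  No CT physics
(streaks, beam hardening) is simulated: the algorithms consume HU bands,
not sinograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .atlas import Frame, mask_bbox
from .core import CTSlice, HU_MAX, HU_MIN

__all__ = [
    "TissueHU",
    "AbdomenPhantomSpec",
    "LiverPhantomSpec",
    "ThighPhantomSpec",
    "LabeledPhantom",
    "make_phantom",
    "make_ensemble",
    "DEFAULT_ABDOMEN_JITTER",
    "DEFAULT_LIVER_JITTER",
    "DEFAULT_THIGH_JITTER",
]

# (mean HU, SD) per tissue; all means inside the global HU bands.
DEFAULT_TISSUE_HU: dict[str, tuple[float, float]] = {
    "air": (-1000.0, 3.0),
    "gas": (-1000.0, 3.0),
    "table": (20.0, 5.0),
    "sat": (-95.0, 10.0),
    "vat": (-95.0, 10.0),
    "back_at": (-95.0, 10.0),
    "muscle_wall": (45.0, 10.0),
    "organ": (35.0, 10.0),
    "spine": (600.0, 40.0),
    "liver": (50.0, 10.0),
    "spleen": (45.0, 10.0),
    "thigh_sat": (-95.0, 10.0),
    "sfat": (-95.0, 10.0),
    "imat": (-95.0, 10.0),
    "thigh_muscle": (45.0, 10.0),
    "fascia": (70.0, 10.0),
    "bone": (1200.0, 50.0),
    "marrow": (-80.0, 10.0),
}

TissueHU = dict[str, tuple[float, float]]

# which truth labels compose each named depot, per station
_DEPOTS = {
    "abdomen": {
        "vat": ("vat",),
        "sat": ("sat",),
        "back_at": ("back_at",),
        "tat": ("vat", "sat"),
        "adipose": ("vat", "sat", "back_at"),
        "muscle": ("muscle_wall",),
    },
    "liver": {
        "liver": ("liver",),
        "spleen": ("spleen",),
    },
    "thigh": {
        "muscle": ("thigh_muscle", "fascia"),  # the fascia is lean tissue
        "sat": ("thigh_sat",),
        "sfat": ("sfat",),
        "imat": ("imat",),
        "adipose": ("thigh_sat", "sfat", "imat"),
        "bone": ("bone", "marrow"),
    },
}


def _grids(shape, spacing):
    yy = np.arange(shape[0])[:, None] * spacing[0] * np.ones((1, shape[1]))
    xx = np.arange(shape[1])[None, :] * spacing[1] * np.ones((shape[0], 1))
    return yy, xx


def _ellipse(yy, xx, cy, cx, semi_y, semi_x):
    return ((xx - cx) / semi_x) ** 2 + ((yy - cy) / semi_y) ** 2 <= 1.0


def _disk(yy, xx, cy, cx, radius):
    return _ellipse(yy, xx, cy, cx, radius, radius)


@dataclass(frozen=True)
class AbdomenPhantomSpec:
    """Parametric abdominal (L4-level) phantom; all geometry in mm."""

    shape: tuple[int, int] = (128, 128)
    spacing: tuple[float, float] = (3.0, 3.0)
    body_cy_mm: float = 180.0
    body_cx_mm: float = 192.0
    body_a_mm: float = 165.0  # lateral semi-axis
    body_b_mm: float = 110.0  # anterior-posterior semi-axis
    sat_thickness_mm: float = 25.0
    wall_thickness_mm: float = 8.0
    wall_gap_mm: float = 0.0  # anterior muscle-wall discontinuity width
    n_organs: int = 4
    organ_semi_mm: tuple[float, float] = (10.0, 22.0)
    spine_semi_mm: tuple[float, float] = (14.0, 16.0)  # (semi_y, semi_x)
    back_muscle_semi_mm: tuple[float, float] = (13.0, 20.0)
    back_at_semi_mm: tuple[float, float] = (6.0, 9.0)
    fill_cavity_with_organ: bool = False  # zero-VAT degenerate variant
    gas_pocket_r_mm: float = 0.0
    table: bool = True
    noise_scale: float = 1.0
    hu_overrides: dict = field(default_factory=dict)
    seed: int = 0

    station = "abdomen"

    def cavity_semiaxes(self) -> tuple[float, float]:
        a = self.body_a_mm - self.sat_thickness_mm - self.wall_thickness_mm
        b = self.body_b_mm - self.sat_thickness_mm - self.wall_thickness_mm
        return b, a

    def validate(self):
        b_cav, a_cav = self.cavity_semiaxes()
        if a_cav <= 40 or b_cav <= 40:
            raise ValueError("inconsistent geometry: cavity too small or inverted")
        if self.body_cy_mm + self.body_b_mm >= self.shape[0] * self.spacing[0] - 15:
            raise ValueError("body does not fit above the table region")


@dataclass(frozen=True)
class LiverPhantomSpec:
    """Liver-level phantom: liver + spleen in a fat-filled cavity."""

    shape: tuple[int, int] = (128, 128)
    spacing: tuple[float, float] = (3.0, 3.0)
    body_cy_mm: float = 180.0
    body_cx_mm: float = 192.0
    body_a_mm: float = 160.0
    body_b_mm: float = 105.0
    sat_thickness_mm: float = 20.0
    wall_thickness_mm: float = 8.0
    liver_hu: float = 50.0  # sweepable over the 0-60 HU range
    liver_a_mm: float = 65.0
    liver_b_mm: float = 52.0
    liver_cx_off_mm: float = -45.0
    liver_cy_off_mm: float = -5.0
    spleen_a_mm: float = 22.0
    spleen_b_mm: float = 15.0
    spleen_cx_off_mm: float = 55.0
    spleen_cy_off_mm: float = 10.0
    spine_semi_mm: tuple[float, float] = (14.0, 16.0)
    back_muscle_semi_mm: tuple[float, float] = (13.0, 20.0)
    table: bool = True
    noise_scale: float = 1.0
    hu_overrides: dict = field(default_factory=dict)
    seed: int = 0

    station = "liver"

    def cavity_semiaxes(self) -> tuple[float, float]:
        a = self.body_a_mm - self.sat_thickness_mm - self.wall_thickness_mm
        b = self.body_b_mm - self.sat_thickness_mm - self.wall_thickness_mm
        return b, a

    def validate(self):
        b_cav, a_cav = self.cavity_semiaxes()
        if a_cav <= 40 or b_cav <= 40:
            raise ValueError("inconsistent geometry: cavity too small or inverted")
        if abs(self.liver_cx_off_mm) + self.liver_a_mm > a_cav + 5:
            raise ValueError("inconsistent geometry: liver exceeds the cavity")


@dataclass(frozen=True)
class ThighPhantomSpec:
    """Mid-thigh phantom: two concentric-structure thighs above a table."""

    shape: tuple[int, int] = (96, 160)
    spacing: tuple[float, float] = (2.5, 2.5)
    center_y_mm: float = 115.0
    center_x_left_mm: float = 105.0
    center_x_right_mm: float = 295.0
    thigh_radius_mm: float = 75.0
    muscle_radius_mm: float = 48.0
    sfat_band_mm: float = 5.0
    fascia_visible: bool = True
    bone_radius_mm: float = 14.0
    cortical_thickness_mm: float = 5.0
    n_imat: int = 4
    imat_radius_mm: tuple[float, float] = (4.0, 7.0)
    bridge: bool = False  # thin tissue bridge joining the thighs
    table: bool = True
    noise_scale: float = 1.0
    hu_overrides: dict = field(default_factory=dict)
    seed: int = 0

    station = "thigh"

    @property
    def fascia_radius_mm(self) -> float:
        return self.muscle_radius_mm + self.sfat_band_mm

    def validate(self):
        fascia_w = min(self.spacing)
        if self.fascia_radius_mm + fascia_w + 4 >= self.thigh_radius_mm:
            raise ValueError("inconsistent geometry: no room for SAT outside the fascia")
        if self.bone_radius_mm + 8 >= self.muscle_radius_mm:
            raise ValueError("inconsistent geometry: bone too large for the muscle compartment")
        if self.center_x_left_mm + self.thigh_radius_mm + 5 >= self.center_x_right_mm - self.thigh_radius_mm:
            raise ValueError("inconsistent geometry: thighs overlap")


PhantomSpec = AbdomenPhantomSpec | LiverPhantomSpec | ThighPhantomSpec


@dataclass
class LabeledPhantom:
    """A synthetic slice plus its ground-truth label map."""

    slice: CTSlice
    labels: np.ndarray
    legend: dict[str, int]
    spec: PhantomSpec
    cavity_frame: Frame | None = None

    def mask(self, name: str) -> np.ndarray:
        if name not in self.legend:
            return np.zeros(self.labels.shape, dtype=bool)
        return self.labels == self.legend[name]

    def _side_mask(self, side: str | None) -> np.ndarray:
        if side is None:
            return np.ones(self.labels.shape, dtype=bool)
        spec = self.spec
        if spec.station != "thigh":
            raise ValueError("side selection only applies to thigh phantoms")
        mid_col = 0.5 * (spec.center_x_left_mm + spec.center_x_right_mm) / spec.spacing[1]
        cols = np.arange(self.labels.shape[1])[None, :] * np.ones((self.labels.shape[0], 1))
        return cols < mid_col if side == "left" else cols >= mid_col

    def depot_mask(self, depot: str, side: str | None = None) -> np.ndarray:
        """Ground-truth mask of a named depot (e.g. 'vat', 'muscle', 'imat')."""
        names = _DEPOTS[self.spec.station].get(depot, (depot,))
        out = np.zeros(self.labels.shape, dtype=bool)
        for name in names:
            out |= self.mask(name)
        return out & self._side_mask(side)

    def truth_area_cm2(self, depot: str, side: str | None = None) -> float:
        sp = self.slice.spacing
        return int(self.depot_mask(depot, side).sum()) * sp[0] * sp[1] / 100.0

    def truth_mean_hu(self, depot: str, side: str | None = None) -> float:
        m = self.depot_mask(depot, side)
        return float(self.slice.pixels[m].mean())

    def truth_table(self) -> dict[str, dict]:
        out = {}
        for depot in _DEPOTS[self.spec.station]:
            m = self.depot_mask(depot)
            out[depot] = {
                "n_pixels": int(m.sum()),
                "area_cm2": self.truth_area_cm2(depot),
                "mean_hu": float(self.slice.pixels[m].mean()) if m.any() else float("nan"),
            }
        return out


def _paint(labels, legend, mask, name):
    if name not in legend:
        legend[name] = len(legend) + 1
    labels[mask] = legend[name]


def _render(spec, labels, legend) -> CTSlice:
    table = dict(DEFAULT_TISSUE_HU)
    table.update(spec.hu_overrides)
    if spec.station == "liver":
        table["liver"] = (spec.liver_hu, table["liver"][1])
    mean = np.full(labels.shape, table["air"][0])
    sd = np.full(labels.shape, table["air"][1])
    for name, idx in legend.items():
        mean[labels == idx] = table[name][0]
        sd[labels == idx] = table[name][1]
    rng = np.random.default_rng(spec.seed)
    pixels = mean + spec.noise_scale * sd * rng.standard_normal(labels.shape)
    return CTSlice(np.clip(pixels, HU_MIN, HU_MAX), spec.spacing, spec.station)


def _paint_table(spec, labels, legend, yy, xx):
    if not spec.table:
        return
    ny = spec.shape[0] * spec.spacing[0]
    nx = spec.shape[1] * spec.spacing[1]
    y_top = max(spec.body_cy_mm + getattr(spec, "body_b_mm", 0.0), 0.85 * ny)
    y_top = min(max(y_top, 0.84 * ny), ny - 12)
    band = (yy >= y_top) & (yy <= y_top + 9.0) & (xx > 0.15 * nx) & (xx < 0.85 * nx)
    _paint(labels, legend, band, "table")


def _paint_back_structures(spec, labels, legend, yy, xx, cy, cx, b_cav, with_back_at):
    spine_sy, spine_sx = spec.spine_semi_mm
    y_sp = cy + b_cav - 10.0
    bm_sy, bm_sx = spec.back_muscle_semi_mm
    for sx_off in (-30.0, 30.0):
        bm = _ellipse(yy, xx, y_sp - 2.0, cx + sx_off, bm_sy, bm_sx)
        _paint(labels, legend, bm, "muscle_wall")
    if with_back_at:
        at_sy, at_sx = spec.back_at_semi_mm
        for sx_off in (-17.0, 17.0):
            at = _ellipse(yy, xx, y_sp - 16.0, cx + sx_off, at_sy, at_sx)
            _paint(labels, legend, at, "back_at")
    spine = _ellipse(yy, xx, y_sp, cx, spine_sy, spine_sx)
    _paint(labels, legend, spine, "spine")
    return y_sp


def _build_abdomen(spec: AbdomenPhantomSpec):
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    yy, xx = _grids(spec.shape, spec.spacing)
    labels = np.zeros(spec.shape, dtype=np.int16)
    legend: dict[str, int] = {}
    cy, cx = spec.body_cy_mm, spec.body_cx_mm
    a, b = spec.body_a_mm, spec.body_b_mm
    b_cav, a_cav = spec.cavity_semiaxes()

    _paint_table(spec, labels, legend, yy, xx)
    _paint(labels, legend, _ellipse(yy, xx, cy, cx, b, a), "sat")
    a_in, b_in = a - spec.sat_thickness_mm, b - spec.sat_thickness_mm
    _paint(labels, legend, _ellipse(yy, xx, cy, cx, b_in, a_in), "muscle_wall")
    cavity = _ellipse(yy, xx, cy, cx, b_cav, a_cav)
    inner_name = "organ" if spec.fill_cavity_with_organ else "vat"
    _paint(labels, legend, cavity, inner_name)

    if spec.wall_gap_mm > 0:
        # carve a narrow anterior discontinuity through the muscle wall
        wall = _ellipse(yy, xx, cy, cx, b_in, a_in) & ~cavity
        r_mid = b_cav + 0.5 * spec.wall_thickness_mm
        dtheta = spec.wall_gap_mm / r_mid
        theta = np.arctan2(-(yy - cy), xx - cx)  # +pi/2 is anterior (up)
        wedge = np.abs(theta - np.pi / 2) <= dtheta / 2
        _paint(labels, legend, wall & wedge, inner_name)

    # organs: lean ellipses in the anterior cavity, clear of the back region
    if not spec.fill_cavity_with_organ:
        lo, hi = spec.organ_semi_mm
        placed = 0
        for _ in range(50 * spec.n_organs):
            if placed >= spec.n_organs:
                break
            sy = rng.uniform(lo, hi)
            sx = rng.uniform(lo, hi)
            ocy = cy + rng.uniform(-0.75, 0.15) * b_cav
            ocx = cx + rng.uniform(-0.7, 0.7) * a_cav
            fits = ((ocx - cx) / max(a_cav - sx, 1e-6)) ** 2 + (
                (ocy - cy) / max(b_cav - sy, 1e-6)
            ) ** 2 <= 1.0
            clear_of_back = ocy + sy < cy + b_cav - 42.0
            if fits and clear_of_back:
                _paint(labels, legend, _ellipse(yy, xx, ocy, ocx, sy, sx), "organ")
                placed += 1

    _paint_back_structures(
        spec, labels, legend, yy, xx, cy, cx, b_cav,
        with_back_at=not spec.fill_cavity_with_organ,
    )

    if spec.gas_pocket_r_mm > 0:
        pocket = _disk(yy, xx, cy - 0.4 * b_cav, cx + 0.3 * a_cav, spec.gas_pocket_r_mm)
        _paint(labels, legend, pocket & cavity, "gas")

    return labels, legend, cavity


def _build_liver(spec: LiverPhantomSpec):
    spec.validate()
    yy, xx = _grids(spec.shape, spec.spacing)
    labels = np.zeros(spec.shape, dtype=np.int16)
    legend: dict[str, int] = {}
    cy, cx = spec.body_cy_mm, spec.body_cx_mm
    a, b = spec.body_a_mm, spec.body_b_mm
    b_cav, a_cav = spec.cavity_semiaxes()

    _paint_table(spec, labels, legend, yy, xx)
    _paint(labels, legend, _ellipse(yy, xx, cy, cx, b, a), "sat")
    a_in, b_in = a - spec.sat_thickness_mm, b - spec.sat_thickness_mm
    _paint(labels, legend, _ellipse(yy, xx, cy, cx, b_in, a_in), "muscle_wall")
    cavity = _ellipse(yy, xx, cy, cx, b_cav, a_cav)
    _paint(labels, legend, cavity, "vat")

    liver = _ellipse(
        yy, xx, cy + spec.liver_cy_off_mm, cx + spec.liver_cx_off_mm, spec.liver_b_mm, spec.liver_a_mm
    )
    _paint(labels, legend, liver & cavity, "liver")
    spleen = _ellipse(
        yy,
        xx,
        cy + spec.spleen_cy_off_mm,
        cx + spec.spleen_cx_off_mm,
        spec.spleen_b_mm,
        spec.spleen_a_mm,
    )
    _paint(labels, legend, spleen & cavity & ~liver, "spleen")

    _paint_back_structures(spec, labels, legend, yy, xx, cy, cx, b_cav, with_back_at=False)
    return labels, legend, cavity


def _build_thigh(spec: ThighPhantomSpec):
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    yy, xx = _grids(spec.shape, spec.spacing)
    labels = np.zeros(spec.shape, dtype=np.int16)
    legend: dict[str, int] = {}
    fascia_w = min(spec.spacing)

    if spec.table:
        ny = spec.shape[0] * spec.spacing[0]
        nx = spec.shape[1] * spec.spacing[1]
        y_top = max(spec.center_y_mm + spec.thigh_radius_mm + 8.0, 0.85 * ny)
        band = (yy >= y_top) & (yy <= y_top + 8.0) & (xx > 0.1 * nx) & (xx < 0.9 * nx)
        _paint(labels, legend, band, "table")

    for ctx in (spec.center_x_left_mm, spec.center_x_right_mm):
        cy = spec.center_y_mm
        _paint(labels, legend, _disk(yy, xx, cy, ctx, spec.thigh_radius_mm), "thigh_sat")
        if spec.fascia_visible:
            _paint(
                labels, legend, _disk(yy, xx, cy, ctx, spec.fascia_radius_mm + fascia_w), "fascia"
            )
        _paint(labels, legend, _disk(yy, xx, cy, ctx, spec.fascia_radius_mm), "sfat")
        _paint(labels, legend, _disk(yy, xx, cy, ctx, spec.muscle_radius_mm), "thigh_muscle")

        # intermuscular fat islands, kept clear of the bone and the compartment rim
        lo, hi = spec.imat_radius_mm
        ring_lo = spec.bone_radius_mm + hi + 3.0
        ring_hi = spec.muscle_radius_mm - hi - 6.0
        centers: list[tuple[float, float]] = []
        for _ in range(60 * spec.n_imat):
            if len(centers) >= spec.n_imat:
                break
            r_isl = rng.uniform(lo, hi)
            rho = rng.uniform(ring_lo, ring_hi)
            phi = rng.uniform(0, 2 * np.pi)
            icy, icx = cy + rho * np.sin(phi), ctx + rho * np.cos(phi)
            if all(np.hypot(icy - py, icx - px) > 2.2 * hi for py, px in centers):
                _paint(labels, legend, _disk(yy, xx, icy, icx, r_isl), "imat")
                centers.append((icy, icx))

        _paint(labels, legend, _disk(yy, xx, cy, ctx, spec.bone_radius_mm), "bone")
        _paint(
            labels,
            legend,
            _disk(yy, xx, cy, ctx, spec.bone_radius_mm - spec.cortical_thickness_mm),
            "marrow",
        )

    if spec.bridge:
        cy = spec.center_y_mm
        band = (np.abs(yy - cy) <= 0.6 * min(spec.spacing)) & (
            xx > spec.center_x_left_mm
        ) & (xx < spec.center_x_right_mm)
        _paint(labels, legend, band & (labels == 0), "thigh_muscle")

    return labels, legend, None


def make_phantom(spec: PhantomSpec) -> LabeledPhantom:
    """Deterministically render a phantom from its spec (geometry + seed)."""
    builders = {"abdomen": _build_abdomen, "liver": _build_liver, "thigh": _build_thigh}
    labels, legend, cavity = builders[spec.station](spec)
    ct = _render(spec, labels, legend)
    frame = mask_bbox(cavity) if cavity is not None else None
    return LabeledPhantom(slice=ct, labels=labels, legend=legend, spec=spec, cavity_frame=frame)


DEFAULT_ABDOMEN_JITTER = {
    "body_a_mm": (150.0, 180.0),
    "body_b_mm": (95.0, 120.0),
    "sat_thickness_mm": (14.0, 34.0),
    "wall_thickness_mm": (5.0, 11.0),
    "n_organs": (2, 6),
}

DEFAULT_LIVER_JITTER = {
    "body_a_mm": (148.0, 172.0),
    "body_b_mm": (95.0, 115.0),
    "sat_thickness_mm": (12.0, 28.0),
    "liver_a_mm": (55.0, 72.0),
    "liver_b_mm": (42.0, 58.0),
    "liver_cx_off_mm": (-55.0, -35.0),
    "liver_cy_off_mm": (-15.0, 5.0),
}

DEFAULT_THIGH_JITTER = {
    "thigh_radius_mm": (64.0, 80.0),
    "muscle_radius_mm": (38.0, 50.0),
    "sfat_band_mm": (3.5, 6.5),
    "n_imat": (2, 5),
}


def make_ensemble(
    base_spec: PhantomSpec,
    n: int,
    jitter: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[LabeledPhantom]:
    """n phantoms with independently jittered geometry, reproducible from seed.

    ``jitter`` maps spec field names to uniform (lo, hi) sampling ranges;
    integer-valued fields are rounded.  Phantom i renders with noise seed
    ``base_spec.seed + i``, so an empty jitter with n=1 reproduces
    ``make_phantom(base_spec)`` exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    jitter = jitter or {}
    field_types = {f.name: f.type for f in fields(base_spec)}
    for name in jitter:
        if name not in field_types:
            raise ValueError(f"unknown spec field in jitter: {name}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        values = {}
        for name, (lo, hi) in jitter.items():
            v = rng.uniform(lo, hi)
            base_val = getattr(base_spec, name)
            values[name] = int(round(v)) if isinstance(base_val, int) else float(v)
        spec_i = replace(base_spec, seed=base_spec.seed + i, **values)
        out.append(make_phantom(spec_i))
    return out
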