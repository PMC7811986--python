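"""Synthetic voxel body phantom for contact-current dosimetry.

A parametric stand-in for a licensed anatomical model, built from geometric
primitives on a uniform voxel grid: trunk as an elliptic cylinder with
concentric skin/fat/muscle layers, limbs as cylinders, two lung ellipsoids,
long bones and a spine, and a heart modelled as an ellipsoidal ventricular
myocardium shell enclosing a blood-filled lumen.  Blood-filled vessel channels
(subclavian, aorta/vena-cava analogues) run from each arm and from the lower
trunk through the myocardium shell into the lumen -- the structure that
channels longitudinal contact currents into the heart.

Seven electrode contact sites (RH, LH, RF, LF, PT, AT, SEAT) are registered as
surface patches; :func:`place_electrode` implements the two contact variants:

* Intern-BM: the skin under the patch is removed so the drive voltage contacts
  the subcutaneous tissue directly;
* Total-BM: additionally a 2-mm slice of the contact electrode adjacent to the
  body carries the voltage-dependent skin properties, and the remaining
  electrode bulk is a 1.0 S/m conductor.

Coordinates: 0-based voxel indices; world position of voxel (i,j,k) center is
``origin + index * spacing`` (mm); axes (x, y, z) = (left-to-right,
posterior-to-anterior, inferior-to-superior).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .contact import BodyModelMode, skin_props
from .tissues import DispersionModel

__all__ = [
    "AIR", "SKIN", "FAT", "MUSCLE", "BONE", "LUNG", "HEART_WALL",
    "HEART_LUMEN", "VESSEL", "ELECTRODE_BULK", "SKIN_SLICE",
    "DEFAULT_TISSUE_MAP", "SITES",
    "PhantomConfig", "VoxelPhantom", "ElectrodePlacement",
    "build_phantom", "place_electrode", "validate_phantom",
    "load_label_volume", "PhantomError",
]

# -- label ids -------------------------------------------------------------
AIR = 0
SKIN = 1
FAT = 2
MUSCLE = 3
BONE = 4
LUNG = 5
HEART_WALL = 6      # ventricular myocardium
HEART_LUMEN = 7     # blood inside the ventricle shell
VESSEL = 8          # blood-filled vessel channels
ELECTRODE_BULK = 9
SKIN_SLICE = 10

DEFAULT_TISSUE_MAP: dict[int, str] = {
    SKIN: "skin",
    FAT: "fat",
    MUSCLE: "muscle",
    BONE: "bone",
    LUNG: "lung",
    HEART_WALL: "heart_muscle",
    HEART_LUMEN: "blood",
    VESSEL: "blood",
    ELECTRODE_BULK: "electrode_bulk",
    SKIN_SLICE: "skin_slice",
}

#: The seven contact sites. "PS" (posterior seat) is accepted as an alias of SEAT.
SITES = ("RH", "LH", "RF", "LF", "PT", "AT", "SEAT")

_ANATOMICAL_LABELS = (SKIN, FAT, MUSCLE, BONE, LUNG, HEART_WALL, HEART_LUMEN)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class PhantomError(ValueError):
    """Configuration or invariant violation of a voxel phantom."""


# -- configuration ---------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """All phantom dimensions in mm.  Defaults give a reduced-stature
    (about 1 m) adult-proportioned body at 4 mm voxels -- large enough to carry
    every anatomical feature at several voxels of resolution while keeping a
    single field solve in the seconds range on one core."""

    spacing_mm: float = 4.0

    # trunk: elliptic cylinder, half axes (x, y), z extent
    trunk_halfwidth: float = 120.0
    trunk_halfdepth: float = 80.0
    trunk_z: tuple[float, float] = (500.0, 900.0)

    # legs: vertical cylinders at x = +-leg_offset
    leg_radius: float = 50.0
    leg_offset: float = 60.0
    leg_z: tuple[float, float] = (0.0, 500.0)

    # arms: horizontal cylinders along x at height arm_z (T pose)
    arm_radius: float = 40.0
    arm_z: float = 820.0
    arm_x: tuple[float, float] = (100.0, 450.0)

    # concentric surface layers
    skin_thickness: float = 4.0
    fat_thickness: float = 8.0

    # heart: myocardium shell = outer ellipsoid minus lumen ellipsoid
    heart_center: tuple[float, float, float] = (-25.0, 15.0, 760.0)
    heart_outer: tuple[float, float, float] = (45.0, 40.0, 50.0)
    heart_lumen: tuple[float, float, float] = (30.0, 26.0, 34.0)

    # pericardial fat sheath around the heart, open below the aperture plane
    # (the apex region, where the heart rests on the diaphragm); 0 disables it
    pericardium_thickness: float = 8.0
    pericardium_aperture: float = 0.7   # fraction of the inferior semi-axis

    # lungs: two ellipsoids
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-55.0, 5.0, 740.0), (55.0, 5.0, 740.0))
    lung_axes: tuple[float, float, float] = (38.0, 48.0, 130.0)

    # bones
    spine_radius: float = 12.0
    spine_y: float = -50.0
    leg_bone_radius: float = 14.0
    arm_bone_radius: float = 10.0
    arm_bone_offset_y: float = 14.0

    # vessel channels (subclavian analogues + aorta/vena-cava analogue)
    vessel_radius: float = 10.0
    vessel_channels: bool = True
    #: perivascular (mediastinal) fat around the course of the vessels;
    #: suppresses current exchange between the channels and the surrounding
    #: muscle so the channels transport the remote contact potential to the
    #: heart instead of tracking the local tissue potential
    vessel_sleeve_thickness: float = 8.0
    #: sleeve the arm course too (a distal pickup segment near the hand
    #: electrode always stays bare); disable in very slender arms where the
    #: sleeve would sever the arm musculature
    vessel_sleeve_in_arm: bool = True

    # electrodes
    patch_size: tuple[float, float] = (100.0, 100.0)
    electrode_bulk_thickness: float = 8.0
    #: per-site window-center offsets (mm) in the two transverse axes
    electrode_offsets: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def tiny(cls, spacing_mm: float = 4.0) -> "PhantomConfig":
        """A small test-scale body (~0.45 m, ~40k body voxels at 4 mm)."""
        return cls(
            spacing_mm=spacing_mm,
            trunk_halfwidth=55.0, trunk_halfdepth=40.0, trunk_z=(220.0, 420.0),
            leg_radius=26.0, leg_offset=28.0, leg_z=(0.0, 220.0),
            arm_radius=22.0, arm_z=380.0, arm_x=(45.0, 200.0),
            heart_center=(-12.0, 0.0, 320.0),
            heart_outer=(30.0, 26.0, 34.0), heart_lumen=(18.0, 15.0, 21.0),
            lung_centers=((-25.0, 0.0, 310.0), (25.0, 0.0, 310.0)),
            lung_axes=(14.0, 20.0, 60.0),
            spine_radius=8.0, spine_y=-18.0,
            leg_bone_radius=8.0, arm_bone_radius=0.0,
            vessel_radius=6.0, vessel_sleeve_in_arm=False,
            patch_size=(50.0, 50.0),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["electrode_offsets"] = {k: list(v) for k, v in self.electrode_offsets.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomConfig":
        d = dict(d)
        for key in ("trunk_z", "leg_z", "arm_x", "heart_center", "heart_outer",
                    "heart_lumen", "lung_axes", "patch_size"):
            if key in d:
                d[key] = tuple(d[key])
        if "lung_centers" in d:
            d["lung_centers"] = tuple(tuple(c) for c in d["lung_centers"])
        if "electrode_offsets" in d:
            d["electrode_offsets"] = {
                k: (float(v[0]), float(v[1])) for k, v in d["electrode_offsets"].items()}
        return cls(**d)

    def with_electrode_offset(self, site: str, d1: float, d2: float) -> "PhantomConfig":
        offsets = dict(self.electrode_offsets)
        base = offsets.get(site, (0.0, 0.0))
        offsets[site] = (base[0] + d1, base[1] + d2)
        return dataclasses.replace(self, electrode_offsets=offsets)

    # -- derived electrode windows ------------------------------------
    def electrode_specs(self) -> dict[str, dict]:
        """Per-site patch: normal axis/sign and window in the transverse axes.

        For each site the window is a rectangle of ``patch_size`` in the two
        axes orthogonal to the patch normal, in world mm.  The transverse axes
        are reported in ascending axis order.
        """
        px, py = self.patch_size
        hx, hy, hz = self.heart_center
        s = self.spacing_mm
        b = self.trunk_halfdepth
        hand_band = (self.arm_z - self.arm_radius - 2 * s, self.arm_z)
        foot_band = (self.leg_z[0] - 2 * s, self.leg_z[0] + 2 * s)
        specs = {
            # hands: underside of the distal arm segment, normal -z; axes (x, y)
            "LH": dict(axis=2, sign=-1, band=hand_band,
                       w1=(-self.arm_x[1], -self.arm_x[1] + px), w2=(-py / 2, py / 2)),
            "RH": dict(axis=2, sign=-1, band=hand_band,
                       w1=(self.arm_x[1] - px, self.arm_x[1]), w2=(-py / 2, py / 2)),
            # feet: bottom of the legs, normal -z; axes (x, y)
            "LF": dict(axis=2, sign=-1, band=foot_band,
                       w1=(-self.leg_offset - px / 2, -self.leg_offset + px / 2),
                       w2=(-py / 2, py / 2)),
            "RF": dict(axis=2, sign=-1, band=foot_band,
                       w1=(self.leg_offset - px / 2, self.leg_offset + px / 2),
                       w2=(-py / 2, py / 2)),
            # thorax patches centered on the heart, normal +-y; axes (x, z)
            "AT": dict(axis=1, sign=+1, band=(b / 2, b + 2 * s),
                       w1=(hx - px / 2, hx + px / 2), w2=(hz - py / 2, hz + py / 2)),
            "PT": dict(axis=1, sign=-1, band=(-b - 2 * s, -b / 2),
                       w1=(hx - px / 2, hx + px / 2), w2=(hz - py / 2, hz + py / 2)),
            # posterior seat: lower posterior trunk, normal -y; axes (x, z)
            "SEAT": dict(axis=1, sign=-1, band=(-b - 2 * s, -b / 2),
                         w1=(-px / 2, px / 2),
                         w2=(self.trunk_z[0] + 10, self.trunk_z[0] + 10 + py)),
        }
        for site, (d1, d2) in self.electrode_offsets.items():
            key = canonical_site(site)
            specs[key]["w1"] = (specs[key]["w1"][0] + d1, specs[key]["w1"][1] + d1)
            specs[key]["w2"] = (specs[key]["w2"][0] + d2, specs[key]["w2"][1] + d2)
        return specs


def canonical_site(site: str) -> str:
    s = site.upper()
    if s == "PS":
        s = "SEAT"
    if s not in SITES:
        raise PhantomError(f"unknown electrode site {site!r}; valid: {SITES} (+ alias PS)")
    return s


# -- phantom container -----------------------------------------------------

@dataclass(frozen=True)
class ElectrodePlacement:
    site: str
    mode: BodyModelMode
    touch_voltage: float
    #: voxels where the drive potential is imposed (Dirichlet set), (N, 3)
    contact: np.ndarray
    #: body-surface footprint of the patch, (N, 3)
    footprint: np.ndarray


@dataclass(frozen=True)
class VoxelPhantom:
    """Labeled voxel volume plus the registries the pipeline needs."""

    labels: np.ndarray                      # (nx, ny, nz) uint8
    spacing: np.ndarray                     # (3,) mm
    origin: np.ndarray                      # (3,) world mm of voxel (0,0,0) center
    tissue_map: dict[int, str]
    electrode_sites: dict[str, np.ndarray]  # site -> (N, 3) surface voxels
    electrode_normals: dict[str, tuple[int, int]]  # site -> (axis, sign)
    heart_axes: np.ndarray                  # (3, 2, 3) world mm endpoints
    config: PhantomConfig | None = None
    electrodes: dict[str, ElectrodePlacement] = field(default_factory=dict)
    slice_material: DispersionModel | None = None

    air_label = AIR

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def body_mask(self) -> np.ndarray:
        return self.labels != AIR

    def tissue_volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume_mm3()

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (mm)."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def face_area_mm2(self, axis: int) -> float:
        other = [a for a in range(3) if a != axis]
        return float(self.spacing[other[0]] * self.spacing[other[1]])

    def patch_area_cm2(self, site: str) -> float:
        site = canonical_site(site)
        axis, _ = self.electrode_normals[site]
        return len(self.electrode_sites[site]) * self.face_area_mm2(axis) / 100.0


# -- geometric primitives --------------------------------------------------

def _grid_1d(lo: float, hi: float, s: float) -> np.ndarray:
    n = int(np.ceil((hi - lo) / s))
    return lo + (np.arange(n) + 0.5) * s


def _capsule_mask(X, Y, Z, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of segment p0-p1 (all mm, broadcast grids)."""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    L2 = float(d @ d)
    # projection parameter clamped to the segment
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = X - (p0[0] + t * d[0])
    dy = Y - (p0[1] + t * d[1])
    dz = Z - (p0[2] + t * d[2])
    return dx * dx + dy * dy + dz * dz <= radius * radius


def _ellipsoid_mask(X, Y, Z, center, axes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


# -- build -----------------------------------------------------------------

def build_phantom(config: PhantomConfig | None = None) -> VoxelPhantom:
    """Rasterize ``config`` into a labeled voxel phantom.

    Deterministic: identical configs give bit-identical label grids.  Raises
    :class:`PhantomError` when the configuration leaves a required tissue
    empty or violates a structural invariant.
    """
    cfg = config or PhantomConfig()
    s = float(cfg.spacing_mm)
    if not 1.0 <= s <= 5.0:
        raise PhantomError(f"spacing must be in [1, 5] mm, got {s}")
    for name, t in (("skin", cfg.skin_thickness), ("fat", cfg.fat_thickness)):
        if t < s:
            raise PhantomError(f"{name} thickness {t} mm is below one voxel ({s} mm)")

    margin = cfg.electrode_bulk_thickness + 2.0 + 2.0 * s
    x = _grid_1d(-cfg.arm_x[1] - margin, cfg.arm_x[1] + margin, s)
    y = _grid_1d(-cfg.trunk_halfdepth - margin, cfg.trunk_halfdepth + margin, s)
    z = _grid_1d(-margin, cfg.trunk_z[1] + margin, s)
    origin = np.array([x[0], y[0], z[0]])
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    # body solid -----------------------------------------------------------
    trunk = (((X / cfg.trunk_halfwidth) ** 2 + (Y / cfg.trunk_halfdepth) ** 2) <= 1.0) \
        & (Z >= cfg.trunk_z[0]) & (Z <= cfg.trunk_z[1])
    legs = np.zeros(trunk.shape, bool)
    for sx in (-1, +1):
        legs |= (((X - sx * cfg.leg_offset) ** 2 + Y ** 2) <= cfg.leg_radius ** 2) \
            & (Z >= cfg.leg_z[0]) & (Z <= cfg.leg_z[1])
    arms = (((Y ** 2 + (Z - cfg.arm_z) ** 2) <= cfg.arm_radius ** 2)
            & (np.abs(X) >= cfg.arm_x[0]) & (np.abs(X) <= cfg.arm_x[1]))
    body = trunk | legs | arms

    # concentric layers ------------------------------------------------------
    n_skin = max(1, int(round(cfg.skin_thickness / s)))
    n_fat = max(1, int(round(cfg.fat_thickness / s)))
    under_skin = ndimage.binary_erosion(body, _STRUCT6, iterations=n_skin, border_value=0)
    under_fat = ndimage.binary_erosion(under_skin, _STRUCT6, iterations=n_fat, border_value=0)

    labels = np.zeros(body.shape, dtype=np.uint8)
    labels[body] = SKIN
    labels[under_skin] = FAT
    labels[under_fat] = MUSCLE

    # bones (over muscle only) ----------------------------------------------
    bones = np.zeros(body.shape, bool)
    bones |= (((X - 0.0) ** 2 + (Y - cfg.spine_y) ** 2) <= cfg.spine_radius ** 2) \
        & (Z >= cfg.trunk_z[0]) & (Z <= cfg.trunk_z[1])
    if cfg.leg_bone_radius > 0:
        for sx in (-1, +1):
            bones |= (((X - sx * cfg.leg_offset) ** 2 + Y ** 2) <= cfg.leg_bone_radius ** 2) \
                & (Z >= cfg.leg_z[0]) & (Z <= cfg.leg_z[1])
    if cfg.arm_bone_radius > 0:
        bones |= ((((Y - cfg.arm_bone_offset_y) ** 2 + (Z - cfg.arm_z) ** 2)
                   <= cfg.arm_bone_radius ** 2)
                  & (np.abs(X) >= cfg.arm_x[0]) & (np.abs(X) <= cfg.arm_x[1]))
    labels[bones & (labels == MUSCLE)] = BONE

    # lungs (over muscle and bone) -------------------------------------------
    lungs = np.zeros(body.shape, bool)
    for c in cfg.lung_centers:
        lungs |= _ellipsoid_mask(X, Y, Z, c, cfg.lung_axes)
    labels[lungs & np.isin(labels, (MUSCLE, BONE))] = LUNG

    # pericardial fat sheath (open below the apex aperture plane) -------------
    if cfg.pericardium_thickness > 0:
        tf = cfg.pericardium_thickness
        sheath = _ellipsoid_mask(
            X, Y, Z, cfg.heart_center, tuple(a + tf for a in cfg.heart_outer))
        z_open = cfg.heart_center[2] - cfg.pericardium_aperture * (cfg.heart_outer[2] + tf)
        sheath &= Z >= z_open
        labels[sheath & np.isin(labels, (MUSCLE, BONE, LUNG))] = FAT

    # perivascular fat sleeve along the trunk course of the vessels ----------
    if cfg.vessel_sleeve_thickness > 0:
        sleeve = np.zeros(body.shape, bool)
        r_sleeve = cfg.vessel_radius + cfg.vessel_sleeve_thickness
        for seg in _vessel_segments(cfg):
            sleeve |= _capsule_mask(X, Y, Z, seg[0], seg[1], r_sleeve)
        if cfg.vessel_sleeve_in_arm:
            # keep a bare distal pickup segment near the hand electrodes
            xa = cfg.arm_x[0] + 0.75 * (cfg.arm_x[1] - cfg.arm_x[0])
            sleeve &= np.abs(X) <= xa - 40.0
        else:
            sleeve &= np.abs(X) <= cfg.trunk_halfwidth
        labels[sleeve & np.isin(labels, (MUSCLE, BONE, LUNG))] = FAT

    # heart shell + lumen ----------------------------------------------------
    heart_outer = _ellipsoid_mask(X, Y, Z, cfg.heart_center, cfg.heart_outer)
    labels[heart_outer & np.isin(labels, (MUSCLE, BONE, LUNG, FAT))] = HEART_WALL
    lumen = _ellipsoid_mask(X, Y, Z, cfg.heart_center, cfg.heart_lumen)
    labels[lumen & (labels == HEART_WALL)] = HEART_LUMEN

    # vessel channels ----------------------------------------------------------
    # (vessel_channels=False is the no-channeling control: the same tubes are
    # rasterized but filled with muscle, leaving everything else identical)
    vessels = np.zeros(body.shape, bool)
    for seg in _vessel_segments(cfg):
        vessels |= _capsule_mask(X, Y, Z, seg[0], seg[1], cfg.vessel_radius)
    paintable = np.isin(labels, (MUSCLE, BONE, LUNG, HEART_WALL, FAT))
    # never breach the skin envelope or the lumen
    labels[vessels & paintable] = VESSEL if cfg.vessel_channels else MUSCLE

    # electrode surface patches --------------------------------------------
    coords = (x, y, z)
    sites: dict[str, np.ndarray] = {}
    normals: dict[str, tuple[int, int]] = {}
    mask = labels != AIR
    for site, spec in cfg.electrode_specs().items():
        axis, sign = spec["axis"], spec["sign"]
        exposed = mask & ~_shift(mask, axis, sign)
        t1, t2 = [a for a in range(3) if a != axis]
        w1lo, w1hi = spec["w1"]
        w2lo, w2hi = spec["w2"]
        sel1 = (coords[t1] >= w1lo) & (coords[t1] <= w1hi)
        sel2 = (coords[t2] >= w2lo) & (coords[t2] <= w2hi)
        sel3 = (coords[axis] >= spec["band"][0]) & (coords[axis] <= spec["band"][1])
        window = (_broadcast_axis(sel1, t1, body.shape)
                  & _broadcast_axis(sel2, t2, body.shape)
                  & _broadcast_axis(sel3, axis, body.shape))
        cand = exposed & window
        # keep only the first exposed face per transverse column, seen from the
        # electrode side, so a patch never wraps onto a second surface
        n_ax = body.shape[axis]
        if sign < 0:
            first = np.argmax(np.moveaxis(cand, axis, -1), axis=-1)
        else:
            first = n_ax - 1 - np.argmax(np.moveaxis(cand, axis, -1)[..., ::-1], axis=-1)
        any_col = np.any(cand, axis=axis)
        keep = np.zeros_like(cand)
        kidx = [None, None, None]
        tgrid = np.nonzero(any_col)
        kidx[t1], kidx[t2] = tgrid
        kidx[axis] = first[tgrid]
        keep[tuple(kidx)] = True
        vox = np.argwhere(cand & keep)
        if vox.size == 0:
            raise PhantomError(f"electrode site {site} has an empty surface patch")
        sites[site] = vox
        normals[site] = (axis, sign)

    # heart axes: three orthogonal trans-cardiac segments through the center
    hc = np.array(cfg.heart_center)
    ax = np.array(cfg.heart_outer)
    heart_axes = np.zeros((3, 2, 3))
    for i in range(3):
        e = np.zeros(3)
        e[i] = 0.9 * ax[i]
        heart_axes[i, 0] = hc - e
        heart_axes[i, 1] = hc + e

    phantom = VoxelPhantom(
        labels=labels,
        spacing=np.array([s, s, s]),
        origin=origin,
        tissue_map=dict(DEFAULT_TISSUE_MAP),
        electrode_sites=sites,
        electrode_normals=normals,
        heart_axes=heart_axes,
        config=cfg,
    )

    required = list(_ANATOMICAL_LABELS) + ([VESSEL] if cfg.vessel_channels else [])
    for lab in required:
        if not np.any(labels == lab):
            raise PhantomError(
                f"configuration leaves required tissue "
                f"{DEFAULT_TISSUE_MAP[lab]!r} (label {lab}) empty")
    validate_phantom(phantom)
    return phantom


def _vessel_segments(cfg: PhantomConfig) -> list[tuple[tuple, tuple]]:
    """Polyline segments of the three vessel channels (world mm)."""
    hc = cfg.heart_center
    az = cfg.arm_z
    ax0, ax1 = cfg.arm_x
    xj = 0.55 * cfg.trunk_halfwidth       # junction well inside the trunk interior
    xa = ax0 + 0.75 * (ax1 - ax0)         # start point well inside the arm
    tz0, tz1 = cfg.trunk_z
    low = (0.0, 0.0, tz0 + 0.08 * (tz1 - tz0))   # lower-trunk end of the aorta analogue
    mid = (hc[0] * 0.4, 0.0, 0.5 * (hc[2] + low[2]))
    segs = []
    for sx in (-1, +1):  # left/right subclavian analogue: along the arm axis
        p_arm = (sx * xa, 0.0, az)        # then down into the heart lumen
        p_junction = (sx * xj, 0.0, az)
        segs.append((p_arm, p_junction))
        segs.append((p_junction, hc))
    # aorta / vena cava analogue: lumen -> lower trunk
    segs.append((hc, mid))
    segs.append((mid, low))
    return segs


def _shift(mask: np.ndarray, axis: int, sign: int) -> np.ndarray:
    """Mask shifted so element i reports the neighbour at i + sign along axis
    (out-of-grid neighbours count as air)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sign > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
    else:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _broadcast_axis(sel: np.ndarray, axis: int, shape: tuple) -> np.ndarray:
    view = [None] * 3
    view[axis] = slice(None)
    return np.broadcast_to(sel[tuple(view)], shape)


# -- electrode placement ----------------------------------------------------

def place_electrode(
    phantom: VoxelPhantom,
    site: str,
    mode: BodyModelMode | str,
    touch_voltage: float,
) -> VoxelPhantom:
    """Return a new phantom with the contact at ``site`` realised.

    Both variants remove the skin under the patch (relabelling it to the first
    tissue found beneath).  TOTAL additionally extrudes the contact electrode
    outward: a 2-mm skin-property slice adjacent to the body, then the
    electrode bulk; the drive potential is imposed on the outer bulk layer.
    INTERN imposes the potential directly on the exposed subcutaneous voxels.

    Placements at disjoint sites commute.
    """
    site = canonical_site(site)
    mode = BodyModelMode(mode) if not isinstance(mode, BodyModelMode) else mode
    if mode not in (BodyModelMode.TOTAL, BodyModelMode.INTERN):
        raise PhantomError(f"placement mode must be TOTAL or INTERN, got {mode}")
    if mode is BodyModelMode.TOTAL and not 25.0 <= touch_voltage <= 220.0:
        raise PhantomError(
            f"TOTAL mode requires touch voltage in [25, 220] V (tabulated skin "
            f"data); got {touch_voltage} V")
    if site not in phantom.electrode_sites:
        raise PhantomError(f"site {site} is not registered on this phantom")

    labels = phantom.labels.copy()
    patch = phantom.electrode_sites[site]
    axis, sign = phantom.electrode_normals[site]
    s_axis = float(phantom.spacing[axis])
    cfg = phantom.config
    n_skin = max(1, int(round((cfg.skin_thickness if cfg else 4.0) / s_axis)))

    # remove the skin under the patch: relabel each column run of skin voxels
    # to the first non-skin tissue beneath it
    step = np.zeros(3, dtype=int)
    step[axis] = -sign  # inward
    depth = n_skin + 3
    cols = patch[:, None, :] + step[None, None, :] * np.arange(depth + 1)[None, :, None]
    for a in range(3):
        np.clip(cols[..., a], 0, labels.shape[a] - 1, out=cols[..., a])
    col_labels = labels[cols[..., 0], cols[..., 1], cols[..., 2]]
    for row in range(patch.shape[0]):
        run = col_labels[row]
        nonskin = np.nonzero(run != SKIN)[0]
        if nonskin.size == 0 or run[nonskin[0]] == AIR:
            # rim column along a side wall: everything in reach is skin
            # (or the column exits the body); expose subcutaneous fat
            first, under = n_skin, FAT
        else:
            first, under = nonskin[0], run[nonskin[0]]
        if first > 0:
            sel = cols[row, :first]
            labels[sel[:, 0], sel[:, 1], sel[:, 2]] = under

    slice_material = phantom.slice_material
    if mode is BodyModelMode.INTERN:
        contact = patch.copy()
    else:
        n_slice = max(1, int(round(2.0 / s_axis)))
        n_bulk = max(1, int(round((cfg.electrode_bulk_thickness if cfg else 8.0) / s_axis)))
        out_step = np.zeros(3, dtype=int)
        out_step[axis] = sign
        contact_list = []
        for d in range(1, n_slice + n_bulk + 1):
            q = patch + out_step * d
            inside = np.all((q >= 0) & (q < np.array(labels.shape)), axis=1)
            q = q[inside]
            free = labels[q[:, 0], q[:, 1], q[:, 2]] == AIR
            q = q[free]
            lab = SKIN_SLICE if d <= n_slice else ELECTRODE_BULK
            labels[q[:, 0], q[:, 1], q[:, 2]] = lab
            if d == n_slice + n_bulk:
                contact_list.append(q)
        contact = np.concatenate(contact_list) if contact_list else np.empty((0, 3), int)
        if contact.size == 0:
            raise PhantomError(f"TOTAL electrode at {site} produced no drive voxels")
        # impedance-preserving slice properties: the voxelized slice is
        # n_slice*spacing thick, so sigma and eps_r are scaled by t/2mm to keep
        # the 2-mm slab impedance
        props = skin_props(touch_voltage)
        factor = n_slice * s_axis / 2.0
        candidate = DispersionModel(
            tissue_name="skin_slice", mode="constant",
            sigma_dc=props.sigma * factor, eps_inf=props.eps_r * factor)
        if slice_material is not None and (
                slice_material.sigma_dc != candidate.sigma_dc
                or slice_material.eps_inf != candidate.eps_inf):
            raise PhantomError(
                "conflicting skin-slice properties: all TOTAL electrodes on one "
                "phantom must share the same touch voltage")
        slice_material = candidate

    electrodes = dict(phantom.electrodes)
    electrodes[site] = ElectrodePlacement(
        site=site, mode=mode, touch_voltage=touch_voltage,
        contact=contact, footprint=patch.copy())
    return dataclasses.replace(
        phantom, labels=labels, electrodes=electrodes, slice_material=slice_material)


# -- validation -------------------------------------------------------------

def validate_phantom(phantom: VoxelPhantom, strict: bool = True) -> list[str]:
    """Check the structural invariants; raise on violation when ``strict``.

    With ``strict=False`` (used for externally loaded label volumes, which may
    contain floating voxels) connectivity problems are reported as warnings
    and returned instead of raised.
    """
    issues: list[str] = []
    labels = phantom.labels

    present = [int(v) for v in np.unique(labels) if v != AIR]
    unmapped = [v for v in present if v not in phantom.tissue_map]
    if unmapped:
        raise PhantomError(f"labels without tissue_map entry: {unmapped}")

    mask = labels != AIR
    _, ncomp = ndimage.label(mask, structure=_STRUCT6)
    if ncomp != 1:
        issues.append(f"body is not a single 6-connected component ({ncomp} parts)")

    # heart shell closure: every lumen voxel may only touch lumen, myocardium
    # or vessel blood.  The vessels-off control variant deliberately plugs the
    # shell penetrations with muscle, so the check is skipped for it.
    lumen = labels == HEART_LUMEN
    closure_applies = phantom.config is None or phantom.config.vessel_channels
    if np.any(lumen) and closure_applies:
        allowed = lumen | (labels == HEART_WALL) | (labels == VESSEL)
        for axis in range(3):
            for sign in (-1, +1):
                neigh_ok = _shift(allowed, axis, sign)
                # voxels at the grid edge have air neighbours -> not ok
                bad = lumen & ~neigh_ok
                if np.any(bad):
                    issues.append(
                        f"heart shell is open: {int(np.count_nonzero(bad))} lumen "
                        f"voxels touch other tissue (axis {axis}, sign {sign})")

    # vessel channels: lumen + vessels must form one component reaching both
    # arms and the lower trunk
    if np.any(labels == VESSEL) and phantom.config is not None:
        cfg = phantom.config
        blood = (labels == VESSEL) | lumen
        comp, n = ndimage.label(blood, structure=_STRUCT6)
        lumen_ids = np.unique(comp[lumen])
        lumen_ids = lumen_ids[lumen_ids != 0]
        if lumen_ids.size != 1:
            issues.append("heart lumen is split across vessel components")
        else:
            reach = np.argwhere(comp == lumen_ids[0])
            wx = reach[:, 0] * phantom.spacing[0] + phantom.origin[0]
            wz = reach[:, 2] * phantom.spacing[2] + phantom.origin[2]
            if not (wx.min() < -cfg.trunk_halfwidth and wx.max() > cfg.trunk_halfwidth):
                issues.append("vessel channels do not reach both arms")
            zlow = cfg.trunk_z[0] + 0.3 * (cfg.trunk_z[1] - cfg.trunk_z[0])
            if not wz.min() < zlow:
                issues.append("vessel channel does not reach the lower trunk")

    # electrode sites: disjoint, plausible areas
    flat = {}
    shape = labels.shape
    for site, vox in phantom.electrode_sites.items():
        f = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
        flat[site] = set(f.tolist())
    site_names = sorted(flat)
    for i, a in enumerate(site_names):
        for b in site_names[i + 1:]:
            if flat[a] & flat[b]:
                issues.append(f"electrode sites {a} and {b} overlap")
    if phantom.config is not None:
        nominal = phantom.config.patch_size[0] * phantom.config.patch_size[1] / 100.0
        for site in phantom.electrode_sites:
            area = phantom.patch_area_cm2(site)
            if not 0.7 * nominal <= area <= 1.3 * nominal:
                issues.append(
                    f"electrode {site} patch area {area:.1f} cm2 outside 30% of "
                    f"nominal {nominal:.1f} cm2")

    # heart axes: pairwise orthogonal, inside the heart bounding box
    axes_v = phantom.heart_axes[:, 1] - phantom.heart_axes[:, 0]
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(float(axes_v[i] @ axes_v[j])) > 1e-9 * (
                    np.linalg.norm(axes_v[i]) * np.linalg.norm(axes_v[j])):
                issues.append(f"heart axes {i} and {j} are not orthogonal")
    heart_vox = np.argwhere((labels == HEART_WALL) | lumen)
    if heart_vox.size:
        lo = phantom.index_to_world(heart_vox.min(axis=0)) - phantom.spacing
        hi = phantom.index_to_world(heart_vox.max(axis=0)) + phantom.spacing
        pts = phantom.heart_axes.reshape(-1, 3)
        if np.any(pts < lo) or np.any(pts > hi):
            issues.append("heart axes leave the heart bounding box")

    if issues:
        if strict:
            raise PhantomError("; ".join(issues))
        for msg in issues:
            warnings.warn(msg, stacklevel=2)
    return issues


# -- external label volumes -------------------------------------------------

def load_label_volume(
    path: str | Path,
    tissue_map: Mapping[int, str],
    heart_axes: np.ndarray | None = None,
    spacing_mm: Sequence[float] | None = None,
) -> VoxelPhantom:
    """Load a labeled voxel volume (NIfTI or HDF5) as a phantom.

    ``tissue_map`` must cover every non-air label present (air is label 0).
    ``heart_axes`` (3 segments, world mm) must be supplied when the file does
    not carry them; they are required for the trans-cardiac field estimate.
    Disconnected bodies are reported as warnings, not errors: real segmented
    models may contain floating voxels.
    """
    from . import io  # local import: io imports phantom types

    labels, spacing, origin, axes_file = io.read_label_volume(path)
    if spacing_mm is not None:
        spacing = np.asarray(spacing_mm, dtype=float)
    if heart_axes is None:
        heart_axes = axes_file
    if heart_axes is None:
        heart_axes = np.zeros((3, 2, 3))
    present = [int(v) for v in np.unique(labels) if v != AIR]
    missing = [v for v in present if v not in tissue_map]
    if missing:
        raise PhantomError(f"labels present but not in tissue_map: {missing}")
    phantom = VoxelPhantom(
        labels=labels.astype(np.uint8),
        spacing=np.asarray(spacing, dtype=float),
        origin=np.asarray(origin, dtype=float),
        tissue_map=dict(tissue_map),
        electrode_sites={},
        electrode_normals={},
        heart_axes=np.asarray(heart_axes, dtype=float),
        config=None,
    )
    validate_phantom(phantom, strict=False)
    return phantom
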