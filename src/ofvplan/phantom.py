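"""Synthetic thoracic phantoms, arc beam geometry, and a pencil-beam influence surrogate.

The phantom is a single axial slice (pseudo-volume via a nominal slice
thickness) holding binary masks for the planning target volume (PTV, the
ipsilateral breast), heart, both lungs, the contralateral breast, and the
external body contour.  Structure sizes and positions are jittered per seed
so a seed sweep emulates a small patient cohort at desk scale.

Coordinate conventions
----------------------
* World frame: x (mm) positive toward the patient's left, y (mm) positive
  toward anterior, origin at the grid center (isocenter).
* Grid: shape ``(ny, nx)``, row-major linearization, 0-based indices;
  row 0 is the most anterior row, column 0 the patient's right.
* Gantry angle per IEC 61217: 0 deg = beam entering from anterior, 90 deg =
  from the patient's left, angles increase clockwise when viewed from the
  patient's feet.  Arcs are traversed from start to stop in the direction
  that sweeps through the anterior (0 deg) direction, giving the extended
  partial arcs used clinically for breast treatments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse

ORGAN_ROLES = ("heart", "lung_ipsi", "lung_contra", "breast_contra")
REQUIRED_ROLES = ("PTV",) + ORGAN_ROLES + ("external",)


class GeometryError(ValueError):
    """Raised when the configured phantom geometry is infeasible."""


@dataclass(frozen=True)
class EllipseSpec:
    """Axis-aligned ellipse: center (x, y) and semi-axes (a, b), all in mm."""

    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the synthetic thorax.

    Nominal ellipses describe a left-sided anatomy; lungs and breasts are
    mirrored in x for right-sided phantoms while the heart stays on the
    patient's left.  ``size_jitter`` scales each semi-axis uniformly in
    ``[1 - j, 1 + j]`` and ``center_jitter_mm`` shifts each center, so the
    structure pseudo-volumes scatter around their nominal values the way
    patient volumes scatter around a cohort mean (scale roughly 1:80
    relative to clinical volumes).
    """

    grid_shape: tuple[int, int] = (128, 128)
    spacing_mm: float = 2.5
    slice_thickness_mm: float = 3.0
    body: EllipseSpec = EllipseSpec((0.0, -10.0), (135.0, 85.0))
    lung: EllipseSpec = EllipseSpec((62.0, -2.0), (52.0, 62.0))
    heart: EllipseSpec = EllipseSpec((12.0, 6.0), (28.0, 46.0))
    breast: EllipseSpec = EllipseSpec((62.0, 76.0), (46.0, 30.0))
    size_jitter: float = 0.08
    center_jitter_mm: float = 5.0
    oar_margin_voxels: int = 1
    pv_range_factor: tuple[float, float] = (0.5, 1.5)

    def nominal_pseudo_volume_cm3(self, role: str) -> float:
        """Analytic ellipse area x slice thickness, in cm^3 (carving ignored)."""
        spec = {"PTV": self.breast, "breast_contra": self.breast,
                "heart": self.heart, "lung_ipsi": self.lung,
                "lung_contra": self.lung, "external": self.body}[role]
        a, b = spec.semi_axes_mm
        return math.pi * a * b * self.slice_thickness_mm / 1000.0

    def target_pseudo_volume_cm3(self, role: str) -> float:
        """Target mean pseudo-volume: the zero-jitter anatomy's volume.

        Unlike the raw ellipse volume this includes the anatomical carving
        (lungs lose the cardiac notch, the PTV is cropped off the organs at
        risk), so it is the value seed sweeps scatter around.
        """
        nominal = replace(self, size_jitter=0.0, center_jitter_mm=0.0)
        return generate_phantom(nominal, seed=0).pseudo_volume_cm3(role)


@dataclass(frozen=True)
class Phantom:
    """Voxelized single-slice thorax with named binary structure masks."""

    grid_shape: tuple[int, int]
    spacing_mm: float
    slice_thickness_mm: float
    masks: dict[str, np.ndarray]
    laterality: str
    seed: int

    @property
    def n_voxels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def voxel_volume_cm3(self) -> float:
        return self.spacing_mm ** 2 * self.slice_thickness_mm / 1000.0

    def pseudo_volume_cm3(self, role: str) -> float:
        return int(self.masks[role].sum()) * self.voxel_volume_cm3

    def voxel_centers_mm(self) -> np.ndarray:
        """(N, 2) array of (x, y) world coordinates of voxel centers."""
        ny, nx = self.grid_shape
        cols = np.arange(nx)
        rows = np.arange(ny)
        x = (cols - (nx - 1) / 2.0) * self.spacing_mm
        y = ((ny - 1) / 2.0 - rows) * self.spacing_mm
        xx, yy = np.meshgrid(x, y)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def world_to_index(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (M, 2) world points to (row, col) indices by nearest voxel center."""
        ny, nx = self.grid_shape
        cols = np.rint(points_mm[:, 0] / self.spacing_mm + (nx - 1) / 2.0).astype(int)
        rows = np.rint((ny - 1) / 2.0 - points_mm[:, 1] / self.spacing_mm).astype(int)
        return rows, cols


def _ellipse_mask(centers: np.ndarray, spec: EllipseSpec, shape: tuple[int, int]) -> np.ndarray:
    cx, cy = spec.center_mm
    a, b = spec.semi_axes_mm
    v = ((centers[:, 0] - cx) / a) ** 2 + ((centers[:, 1] - cy) / b) ** 2
    return (v <= 1.0).reshape(shape)


def _jitter(spec: EllipseSpec, rng: np.random.Generator, size_jitter: float,
            center_jitter: float) -> EllipseSpec:
    scale = rng.uniform(1.0 - size_jitter, 1.0 + size_jitter, size=2)
    shift = rng.uniform(-center_jitter, center_jitter, size=2)
    return EllipseSpec(
        (spec.center_mm[0] + shift[0], spec.center_mm[1] + shift[1]),
        (spec.semi_axes_mm[0] * scale[0], spec.semi_axes_mm[1] * scale[1]),
    )


def _mirror_x(spec: EllipseSpec) -> EllipseSpec:
    return EllipseSpec((-spec.center_mm[0], spec.center_mm[1]), spec.semi_axes_mm)


def generate_phantom(config: PhantomConfig = PhantomConfig(), seed: int = 0,
                     laterality: str = "left") -> Phantom:
    """Generate a seeded synthetic thoracic phantom.

    Raises
    ------
    GeometryError
        If the configured ranges are infeasible (an organ larger than the
        body, an empty PTV, or a structure outside its pseudo-volume band).
    """
    if laterality not in ("left", "right"):
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    for name, spec in (("lung", config.lung), ("heart", config.heart),
                       ("breast", config.breast)):
        if (spec.semi_axes_mm[0] >= config.body.semi_axes_mm[0]
                or spec.semi_axes_mm[1] >= config.body.semi_axes_mm[1]):
            raise GeometryError(
                f"{name} semi-axes {spec.semi_axes_mm} exceed body "
                f"semi-axes {config.body.semi_axes_mm}")

    rng = np.random.default_rng(seed)
    # Fixed draw order keeps seeds reproducible if downstream code changes.
    body = _jitter(config.body, rng, config.size_jitter, config.center_jitter_mm)
    lung_i = _jitter(config.lung, rng, config.size_jitter, config.center_jitter_mm)
    lung_c = _mirror_x(_jitter(config.lung, rng, config.size_jitter, config.center_jitter_mm))
    heart = _jitter(config.heart, rng, config.size_jitter, config.center_jitter_mm)
    breast_i = _jitter(config.breast, rng, config.size_jitter, config.center_jitter_mm)
    breast_c = _mirror_x(_jitter(config.breast, rng, config.size_jitter, config.center_jitter_mm))
    if laterality == "right":
        lung_i, lung_c = _mirror_x(lung_i), _mirror_x(lung_c)
        breast_i, breast_c = _mirror_x(breast_i), _mirror_x(breast_c)

    shape = config.grid_shape
    tmp = Phantom(shape, config.spacing_mm, config.slice_thickness_mm, {},
                  laterality, seed)
    centers = tmp.voxel_centers_mm()

    external = (_ellipse_mask(centers, body, shape)
                | _ellipse_mask(centers, breast_i, shape)
                | _ellipse_mask(centers, breast_c, shape))
    heart_m = _ellipse_mask(centers, heart, shape) & external
    lung_i_m = _ellipse_mask(centers, lung_i, shape) & external & ~heart_m
    lung_c_m = _ellipse_mask(centers, lung_c, shape) & external & ~heart_m
    oars = heart_m | lung_i_m | lung_c_m
    oars_dilated = ndimage.binary_dilation(oars, iterations=config.oar_margin_voxels)
    ptv = _ellipse_mask(centers, breast_i, shape) & external & ~oars_dilated
    breast_c_m = (_ellipse_mask(centers, breast_c, shape) & external
                  & ~oars_dilated & ~ptv)

    masks = {"PTV": ptv, "heart": heart_m, "lung_ipsi": lung_i_m,
             "lung_contra": lung_c_m, "breast_contra": breast_c_m,
             "external": external}
    phantom = replace(tmp, masks=masks)

    lo, hi = config.pv_range_factor
    for role in REQUIRED_ROLES:
        if not masks[role].any():
            raise GeometryError(f"structure {role!r} is empty under this configuration")
        if role == "external":
            continue
        pv = phantom.pseudo_volume_cm3(role)
        nominal = config.nominal_pseudo_volume_cm3(role)
        if not (lo * nominal <= pv <= hi * nominal):
            raise GeometryError(
                f"{role} pseudo-volume {pv:.1f} cm^3 outside "
                f"[{lo * nominal:.1f}, {hi * nominal:.1f}] cm^3")
    return phantom


# ---------------------------------------------------------------------------
# Beam geometry


@dataclass(frozen=True)
class BeamSet:
    """Coplanar arc beam geometry: control angles plus per-angle beamlet offsets.

    ``offsets_mm[i]`` are the lateral beamlet positions (at the isocenter
    plane) for ``gantry_angles[i]``; they span the PTV projection at that
    angle plus a margin.
    """

    gantry_angles: tuple[float, ...]
    beamlets_per_angle: int
    offsets_mm: tuple[tuple[float, ...], ...]
    source_distance_mm: float
    arc_start: float
    arc_stop: float
    grid_shape: tuple[int, int]

    @property
    def n_beamlets(self) -> int:
        return len(self.gantry_angles) * self.beamlets_per_angle


DEFAULT_ARCS = {"left": (180.0, 288.0), "right": (180.0, 72.0)}


def _arc_angles(arc_start: float, arc_stop: float, n_angles: int) -> tuple[float, ...]:
    span_inc = (arc_stop - arc_start) % 360.0
    span_dec = (arc_start - arc_stop) % 360.0
    if span_inc == 0.0 and span_dec == 0.0:
        raise ValueError("arc span of zero degrees")
    inc_has_anterior = (0.0 - arc_start) % 360.0 <= span_inc
    dec_has_anterior = (arc_start - 0.0) % 360.0 <= span_dec
    if inc_has_anterior or not dec_has_anterior:
        step, span = 1.0, span_inc
    else:
        step, span = -1.0, span_dec
    ks = np.linspace(0.0, span, n_angles)
    return tuple(float((arc_start + step * k) % 360.0) for k in ks)


def _beam_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Source direction and in-plane perpendicular for a gantry angle."""
    th = math.radians(angle_deg)
    src_dir = np.array([math.sin(th), math.cos(th)])   # isocenter -> source
    perp = np.array([math.cos(th), -math.sin(th)])     # lateral axis at isocenter
    return src_dir, perp


def build_beamset(phantom: Phantom, arc_start: float | None = None,
                  arc_stop: float | None = None, n_angles: int = 28,
                  beamlets_per_angle: int = 24, margin_mm: float = 10.0,
                  source_distance_mm: float = 1000.0) -> BeamSet:
    """Evenly spaced control angles over the arc plus lateral beamlet offsets.

    Offsets are chosen to span the PTV's projected extent at every control
    angle plus ``margin_mm`` on either side.
    """
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")
    if arc_start is None or arc_stop is None:
        arc_start, arc_stop = DEFAULT_ARCS[phantom.laterality]
    angles = _arc_angles(arc_start, arc_stop, n_angles)

    centers = phantom.voxel_centers_mm()[phantom.masks["PTV"].ravel()]
    offsets = []
    for ang in angles:
        _, perp = _beam_axes(ang)
        w = centers @ perp
        offsets.append(tuple(np.linspace(float(w.min()) - margin_mm,
                                         float(w.max()) + margin_mm,
                                         beamlets_per_angle)))
    return BeamSet(angles, beamlets_per_angle, tuple(offsets),
                   source_distance_mm, float(arc_start), float(arc_stop),
                   phantom.grid_shape)


# ---------------------------------------------------------------------------
# Influence matrix


@dataclass(frozen=True)
class InfluenceMatrix:
    """Beamlet-to-voxel dose deposition coefficients (Gy per unit fluence).

    ``matrix`` is CSR with shape (n_beamlets, n_voxels); voxels are the
    row-major linearization of the phantom grid.  Coefficients are zero
    outside the external contour.
    """

    matrix: sparse.csr_matrix
    beamlet_index: tuple[tuple[float, float], ...]  # (gantry angle, lateral offset)
    grid_shape: tuple[int, int]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[0]


def compute_influence(phantom: Phantom, beamset: BeamSet,
                      attenuation_per_mm: float = 0.005,
                      lateral_sigma_mm: float = 3.0,
                      cutoff_sigmas: float = 2.5,
                      halo_amplitude: float = 0.012,
                      halo_sigma_mm: float = 80.0) -> InfluenceMatrix:
    """Pencil-beam surrogate dose model.

    Each beamlet is a divergent ray from the source through its lateral
    offset at the isocenter plane.  Dose falls off exponentially with depth
    from the external-contour entry point (found by ray marching at
    half-voxel steps) and spreads laterally as a double Gaussian: a narrow
    primary core (``lateral_sigma_mm``) plus a weak, broad scatter halo
    (``halo_amplitude`` relative amplitude, ``halo_sigma_mm`` width).  The
    halo reproduces the unavoidable low-dose bath of a real beam; set
    ``halo_amplitude = 0`` for a pure single-Gaussian pencil beam.
    """
    if attenuation_per_mm <= 0 or lateral_sigma_mm <= 0:
        raise ValueError("attenuation and lateral sigma must be positive")
    if halo_amplitude < 0 or halo_sigma_mm <= 0:
        raise ValueError("halo amplitude must be >= 0 and halo sigma positive")
    if beamset.grid_shape != phantom.grid_shape:
        raise ValueError("beamset was built for a different grid shape")

    centers = phantom.voxel_centers_mm()
    external = phantom.masks["external"].ravel()
    ny, nx = phantom.grid_shape
    n_vox = ny * nx
    R = beamset.source_distance_mm
    half_extent = 0.5 * math.hypot(nx, ny) * phantom.spacing_mm + phantom.spacing_mm
    march = np.arange(R - half_extent, R + half_extent, phantom.spacing_mm / 2.0)
    cutoff = cutoff_sigmas * (halo_sigma_mm if halo_amplitude > 0 else lateral_sigma_mm)

    rows, cols, vals = [], [], []
    index = []
    b = 0
    for ang, angle_offsets in zip(beamset.gantry_angles, beamset.offsets_mm):
        src_dir, perp = _beam_axes(ang)
        source = R * src_dir
        for w in angle_offsets:
            target = w * perp
            u = target - source
            u /= np.linalg.norm(u)
            uperp = np.array([u[1], -u[0]])
            # entry point: first marched sample whose voxel center is inside
            pts = source[None, :] + march[:, None] * u[None, :]
            r_idx, c_idx = phantom.world_to_index(pts)
            ok = (r_idx >= 0) & (r_idx < ny) & (c_idx >= 0) & (c_idx < nx)
            inside = np.zeros(march.shape, dtype=bool)
            lin = r_idx[ok] * nx + c_idx[ok]
            inside[ok] = external[lin]
            hits = np.nonzero(inside)[0]
            index.append((ang, float(w)))
            b += 1
            if hits.size == 0:
                continue  # beamlet misses the body entirely
            s_entry = march[hits[0]]

            rel = centers - source
            s = rel @ u
            t = rel @ uperp
            sel = external & (np.abs(t) <= cutoff) & (s >= s_entry)
            if not sel.any():
                continue
            depth = s[sel] - s_entry
            lateral = np.exp(-0.5 * (t[sel] / lateral_sigma_mm) ** 2)
            if halo_amplitude > 0:
                lateral = lateral + halo_amplitude * np.exp(
                    -0.5 * (t[sel] / halo_sigma_mm) ** 2)
            coeff = np.exp(-attenuation_per_mm * depth) * lateral
            vox = np.nonzero(sel)[0]
            rows.append(np.full(vox.shape, b - 1))
            cols.append(vox)
            vals.append(coeff)

    if rows:
        mat = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(b, n_vox))
    else:
        mat = sparse.csr_matrix((b, n_vox))
    return InfluenceMatrix(mat, tuple(index), phantom.grid_shape)
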