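"""Synthetic temporal-bone sodium phantoms.

The inner-ear fluid spaces carry a huge sodium contrast: endolymph holds
~1.3 mM of Na+ while perilymph and CSF are plasma-like (~141-148 mM).
Endolymphatic hydrops expands the endolymphatic space into the perilymphatic
space, so a hydropic ear loses sodium signal relative to its partner.  The
phantoms built here encode exactly that statistical structure: two mirrored
parametric inner ears (spiral cochlea, ellipsoidal vestibule, cylindrical
internal auditory meatus) embedded in bone and brain, with a per-side
``hydrops_fraction`` that reassigns fluid voxels from perilymph to endolymph
at constant total fluid volume, plus a bounded off-resonance map that drives
bSSFP banding downstream.

Geometry is deliberately coarse parametric solid modelling: at the 2 mm
acquisition resolution of the sodium scan only ROI-scale statistics matter,
not cochlear microanatomy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Tissue",
    "CompartmentSpec",
    "DEFAULT_COMPARTMENTS",
    "EarGeometry",
    "B0Params",
    "PhantomSpec",
    "PhantomVolume",
    "build_phantom",
    "hydrops_series",
]


class Tissue(IntEnum):
    """Voxel label legend (value order is part of the file format)."""

    BACKGROUND = 0
    BONE = 1
    CSF = 2          # IAM / cerebello-pontine angle fluid
    PERILYMPH = 3
    ENDOLYMPH = 4
    BRAIN = 5


@dataclass(frozen=True)
class CompartmentSpec:
    """Sodium content and relaxation constants for one tissue class.

    Concentrations are in mM; relaxation times in ms.  Sodium relaxation
    times of inner-ear fluid are not established in the literature; the
    defaults below are declared assumptions (free-fluid-like for the
    lymphatic spaces and CSF, short biexponential-averaged values for
    brain tissue) chosen so that fluid T2* far exceeds the 2 ms readout
    while solid-tissue T2* is shorter than it.
    """

    label: Tissue
    sodium_concentration: float
    t1: float
    t2: float
    t2star: float

    def __post_init__(self) -> None:
        if self.sodium_concentration < 0:
            raise ValueError("sodium_concentration must be >= 0")
        if not (0 < self.t2star <= self.t2 <= self.t1):
            raise ValueError(
                f"need 0 < t2star <= t2 <= t1, got "
                f"{self.t2star}/{self.t2}/{self.t1} for {self.label.name}"
            )


#: Versioned default compartment table.  Endolymph 1.3 mM vs perilymph
#: 145 mM (midpoint of the 141-148 mM physiological range); CSF matches
#: perilymph; brain at a typical tissue sodium concentration.
DEFAULT_COMPARTMENTS: dict[Tissue, CompartmentSpec] = {
    Tissue.BACKGROUND: CompartmentSpec(Tissue.BACKGROUND, 0.0, 1000.0, 100.0, 50.0),
    Tissue.BONE: CompartmentSpec(Tissue.BONE, 0.0, 20.0, 2.0, 0.5),
    Tissue.CSF: CompartmentSpec(Tissue.CSF, 145.0, 60.0, 55.0, 50.0),
    Tissue.PERILYMPH: CompartmentSpec(Tissue.PERILYMPH, 145.0, 60.0, 55.0, 50.0),
    Tissue.ENDOLYMPH: CompartmentSpec(Tissue.ENDOLYMPH, 1.3, 60.0, 55.0, 50.0),
    Tissue.BRAIN: CompartmentSpec(Tissue.BRAIN, 40.0, 35.0, 20.0, 4.0),
}


@dataclass(frozen=True)
class EarGeometry:
    """Parametric solid model of one inner ear, in ear-local mm.

    The cochlea is a spiral tube (2.5 turns, shrinking radius), the
    vestibule an ellipsoid, the IAM a cylinder running medially from the
    vestibule.  Defaults are tuned so that, voxelised at 1 mm, the cochlea
    mask volume sits near 83 mm^3 and the vestibule near 47 mm^3 --
    inside the ranges reported by human observers (63-110 and 31-59 mm^3).
    """

    cochlea_center: tuple[float, float, float] = (2.0, 6.0, -2.5)
    cochlea_base_radius: float = 3.2       # spiral radius at the base turn, mm
    cochlea_taper: float = 0.55            # fractional radius loss apex vs base
    cochlea_turns: float = 2.5
    cochlea_tube_radius: float = 0.86      # lumen radius, mm
    vestibule_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    vestibule_semiaxes: tuple[float, float, float] = (2.8, 2.2, 1.8)
    iam_radius: float = 2.5                # mm
    iam_length: float = 10.0               # mm, runs medially from the ear
    bone_margin: float = 4.0               # otic-capsule shell thickness, mm


@dataclass(frozen=True)
class B0Params:
    """Off-resonance model: smooth low-order field plus interface perturbation.

    ``amplitude_hz`` bounds the final map (the sum is clipped);
    ``boundary_amplitude_hz`` scales a Gaussian-blurred perturbation at
    bone-fluid interfaces, emulating susceptibility gradients at the skull
    base.  A default amplitude of 150 Hz produces visible bands inside the
    -100..+200 Hz reconstruction sweep for the 14.26 ms TR (band period
    1/TR = 70 Hz).
    """

    amplitude_hz: float = 150.0
    length_scale_mm: float = 40.0
    boundary_amplitude_hz: float = 60.0
    boundary_blur_mm: float = 2.0
    constant_hz: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic head; a spec + seed is reproducible."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 1.0                       # mm, isotropic
    ear_offset: float = 26.0                      # |x| of each ear centre, mm
    ear_geometry: EarGeometry = field(default_factory=EarGeometry)
    hydrops_fraction: tuple[float, float] = (0.2, 0.2)   # (left, right)
    b0_params: B0Params = field(default_factory=B0Params)
    compartments: tuple[CompartmentSpec, ...] = tuple(DEFAULT_COMPARTMENTS.values())
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape must be three axes of at least 4 voxels")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        for f in self.hydrops_fraction:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"hydrops_fraction {f} outside [0, 1]")
        half_fov = min(n * self.voxel_size for n in self.grid_shape) / 2.0
        g = self.ear_geometry
        reach = self.ear_offset + g.cochlea_base_radius + g.bone_margin + max(
            abs(c) for c in g.cochlea_center
        )
        if reach >= half_fov:
            raise ValueError(
                f"ear geometry (reach {reach:.1f} mm) does not fit the "
                f"{2 * half_fov:.0f} mm field of view"
            )

    @property
    def compartment_table(self) -> dict[Tissue, CompartmentSpec]:
        return {c.label: c for c in self.compartments}


@dataclass
class PhantomVolume:
    """Voxelised ground truth: concentration, relaxation, field and labels."""

    concentration_map: np.ndarray     # mM
    t1_map: np.ndarray                # ms
    t2_map: np.ndarray                # ms
    t2star_map: np.ndarray            # ms
    offres_map: np.ndarray            # Hz
    label_map: np.ndarray             # Tissue codes, int8
    affine: np.ndarray                # 4x4 voxel -> world (RAS+, mm)
    spec: PhantomSpec

    # per-side structure masks keyed (structure, side), filled by build_phantom
    structure_masks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        return float(self.spec.voxel_size**3)

    def mask(self, structure: str, side: str) -> np.ndarray:
        """Binary mask of ``structure`` in {cochlea, vestibule, iam, inner_ear}
        on ``side`` in {left, right}."""
        key = (structure.lower(), side.lower())
        if key not in self.structure_masks:
            raise KeyError(f"no mask for {key}; have {sorted(self.structure_masks)}")
        return self.structure_masks[key]

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates (mm) as broadcastable arrays."""
        n = self.label_map.shape
        ax = []
        for i in range(3):
            idx = np.arange(n[i], dtype=float)
            ax.append(idx * self.affine[i, i] + self.affine[i, 3])
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )


def _world_axes(shape: tuple[int, int, int], voxel: float) -> list[np.ndarray]:
    # world origin at voxel index n//2 on each axis (matches the FFT-centred
    # convention used by the reconstruction grid)
    return [(np.arange(n, dtype=float) - n // 2) * voxel for n in shape]


def _phantom_affine(shape: tuple[int, int, int], voxel: float) -> np.ndarray:
    aff = np.diag([voxel, voxel, voxel, 1.0])
    for i, n in enumerate(shape):
        aff[i, 3] = -(n // 2) * voxel
    return aff


def _cochlea_curve(g: EarGeometry, n_pts: int = 600) -> np.ndarray:
    """Sample the cochlear spiral centreline (ear-local mm)."""
    t = np.linspace(0.0, 1.0, n_pts)
    radius = g.cochlea_base_radius * (1.0 - g.cochlea_taper * t)
    phi = 2.0 * np.pi * g.cochlea_turns * t
    cx, cy, cz = g.cochlea_center
    x = cx + 1.6 * t                      # modest apical drift
    y = cy + radius * np.cos(phi)
    z = cz + radius * np.sin(phi)
    return np.column_stack([x, y, z])


def _ear_masks(
    spec: PhantomSpec, side: str
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Voxelise one ear.  Returns (masks, cochlea_axis_dist, vestibule_dist).

    The distance arrays (mm, over the respective fluid masks' full grid)
    order fluid voxels from the structure core outwards; the hydrops model
    converts the innermost fraction to endolymph.
    """
    g = spec.ear_geometry
    sign = -1.0 if side == "left" else 1.0
    ax = _world_axes(spec.grid_shape, spec.voxel_size)
    # ear-local coordinates; the left ear is the exact mirror image (x -> -x)
    xl, yl, zl = np.meshgrid(
        sign * ax[0] - spec.ear_offset, ax[1], ax[2], indexing="ij"
    )

    # vestibule: ellipsoid
    vc = np.asarray(g.vestibule_center)
    va = np.asarray(g.vestibule_semiaxes)
    vest_d2 = (
        ((xl - vc[0]) / va[0]) ** 2
        + ((yl - vc[1]) / va[1]) ** 2
        + ((zl - vc[2]) / va[2]) ** 2
    )
    vestibule = vest_d2 <= 1.0
    vest_dist = np.sqrt(vest_d2) * float(np.mean(va))  # ~mm from centre

    # cochlea: tube around the spiral centreline, via KD-tree on curve samples
    curve = _cochlea_curve(g)
    bbox_lo = curve.min(axis=0) - 2.0 * g.cochlea_tube_radius
    bbox_hi = curve.max(axis=0) + 2.0 * g.cochlea_tube_radius
    inside_box = (
        (xl >= bbox_lo[0]) & (xl <= bbox_hi[0])
        & (yl >= bbox_lo[1]) & (yl <= bbox_hi[1])
        & (zl >= bbox_lo[2]) & (zl <= bbox_hi[2])
    )
    pts = np.column_stack([xl[inside_box], yl[inside_box], zl[inside_box]])
    coch_dist = np.full(spec.grid_shape, np.inf)
    if pts.size:
        d, _ = cKDTree(curve).query(pts, k=1)
        coch_dist[inside_box] = d
    cochlea = coch_dist <= g.cochlea_tube_radius
    cochlea &= ~vestibule  # vestibule wins any overlap

    # IAM: cylinder along x running medially from the vestibular region
    x0 = -g.iam_length - 2.0
    iam = (
        (xl >= x0)
        & (xl <= x0 + g.iam_length)
        & ((yl - vc[1]) ** 2 + (zl - vc[2]) ** 2 <= g.iam_radius**2)
    )
    iam &= ~(vestibule | cochlea)
    # lateral half of the IAM (the reference ROI used for scaling)
    iam_lateral = iam & (xl >= x0 + g.iam_length / 2.0)

    masks = {
        "cochlea": cochlea,
        "vestibule": vestibule,
        "iam": iam,
        "iam_lateral": iam_lateral,
        "inner_ear": cochlea | vestibule,
    }
    return masks, coch_dist, vest_dist


def _assign_endolymph(
    fluid_mask: np.ndarray, core_dist: np.ndarray, fraction: float
) -> np.ndarray:
    """Innermost ``fraction`` of fluid voxels (by core distance) -> endolymph.

    Voxel counts are conserved exactly: len(endolymph) = round(f * n_fluid).
    """
    idx = np.flatnonzero(fluid_mask.ravel())
    if idx.size == 0:
        return np.zeros_like(fluid_mask)
    n_endo = int(round(fraction * idx.size))
    order = np.argsort(core_dist.ravel()[idx], kind="stable")
    endo = np.zeros(fluid_mask.size, dtype=bool)
    endo[idx[order[:n_endo]]] = True
    return endo.reshape(fluid_mask.shape)


def _offres_map(spec: PhantomSpec, label_map: np.ndarray) -> np.ndarray:
    b0 = spec.b0_params
    rng = np.random.default_rng(np.random.SeedSequence([spec.noise_seed, 0xB0]))
    ax = _world_axes(spec.grid_shape, spec.voxel_size)
    scale = max(b0.length_scale_mm, 1e-6)
    u = ax[0][:, None, None] / scale
    v = ax[1][None, :, None] / scale
    w = ax[2][None, None, :] / scale
    # low-order smooth polynomial with seeded coefficients
    coeffs = rng.normal(size=9)
    smooth = (
        coeffs[0] * u + coeffs[1] * v + coeffs[2] * w
        + coeffs[3] * u * v + coeffs[4] * u * w + coeffs[5] * v * w
        + coeffs[6] * (u**2 - 0.5) + coeffs[7] * (v**2 - 0.5) + coeffs[8] * (w**2 - 0.5)
    )
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth *= 0.7 * b0.amplitude_hz / peak

    # local perturbation at bone-fluid interfaces
    fluid = np.isin(label_map, (Tissue.CSF, Tissue.PERILYMPH, Tissue.ENDOLYMPH))
    bone = label_map == Tissue.BONE
    interface = ndimage.binary_dilation(bone) & ndimage.binary_dilation(fluid)
    bump = np.zeros(spec.grid_shape)
    if interface.any() and b0.boundary_amplitude_hz > 0:
        bump[interface] = rng.normal(size=int(interface.sum()))
        bump = ndimage.gaussian_filter(bump, b0.boundary_blur_mm / spec.voxel_size)
        peak = np.abs(bump).max()
        if peak > 0:
            bump *= b0.boundary_amplitude_hz / peak

    total = np.clip(smooth + bump, -b0.amplitude_hz, b0.amplitude_hz)
    return total + b0.constant_hz


def build_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Voxelise a two-eared temporal-bone phantom from ``spec``.

    Deterministic for a fixed spec (the only randomness -- off-resonance
    texture -- is drawn from ``spec.noise_seed``).  The hydropic side's
    endolymph is enlarged at the expense of perilymph, holding the total
    fluid volume of each structure fixed.
    """
    table = spec.compartment_table
    label = np.zeros(spec.grid_shape, dtype=np.int8)
    structure_masks: dict[tuple[str, str], np.ndarray] = {}
    endo_by_side: dict[str, np.ndarray] = {}
    fluid_all = np.zeros(spec.grid_shape, dtype=bool)

    for side, frac in (("left", spec.hydrops_fraction[0]),
                       ("right", spec.hydrops_fraction[1])):
        masks, coch_dist, vest_dist = _ear_masks(spec, side)
        for name in ("cochlea", "vestibule", "iam", "iam_lateral", "inner_ear"):
            structure_masks[(name, side)] = masks[name]
        endo = _assign_endolymph(masks["cochlea"], coch_dist, frac)
        endo |= _assign_endolymph(masks["vestibule"], vest_dist, frac)
        endo_by_side[side] = endo
        fluid_all |= masks["inner_ear"] | masks["iam"]

    # bone shell around each ear's fluid, then a brain blob, then labels
    bone = ndimage.binary_dilation(
        fluid_all, iterations=max(1, int(round(spec.ear_geometry.bone_margin
                                               / spec.voxel_size)))
    ) & ~fluid_all

    ax = _world_axes(spec.grid_shape, spec.voxel_size)
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    half = [n * spec.voxel_size / 2.0 for n in spec.grid_shape]
    brain = ((x / (0.88 * half[0])) ** 2 + (y / (0.82 * half[1])) ** 2
             + ((z - 0.1 * half[2]) / (0.72 * half[2])) ** 2) <= 1.0

    label[brain] = Tissue.BRAIN
    label[bone] = Tissue.BONE
    for side in ("left", "right"):
        label[structure_masks[("iam", side)]] = Tissue.CSF
        inner = structure_masks[("inner_ear", side)]
        label[inner] = Tissue.PERILYMPH
        label[endo_by_side[side]] = Tissue.ENDOLYMPH

    shape = spec.grid_shape
    conc = np.zeros(shape)
    t1 = np.empty(shape)
    t2 = np.empty(shape)
    t2s = np.empty(shape)
    for tissue, comp in table.items():
        m = label == tissue
        conc[m] = comp.sodium_concentration
        t1[m] = comp.t1
        t2[m] = comp.t2
        t2s[m] = comp.t2star

    return PhantomVolume(
        concentration_map=conc,
        t1_map=t1,
        t2_map=t2,
        t2star_map=t2s,
        offres_map=_offres_map(spec, label),
        label_map=label,
        affine=_phantom_affine(shape, spec.voxel_size),
        spec=spec,
        structure_masks=structure_masks,
    )


def hydrops_series(spec: PhantomSpec, fractions: list[float]) -> list[PhantomVolume]:
    """One phantom per endolymph fraction (applied to both sides), all other
    parameters and the seed held fixed."""
    if not fractions:
        raise ValueError("fractions must be a non-empty list")
    out = []
    for f in fractions:
        out.append(build_phantom(dataclasses.replace(spec, hydrops_fraction=(f, f))))
    return out
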