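"""Synthetic infarcted-ventricle phantoms with ground-truth channel geometry.

The study's ex-vivo MR segmentations are not publicly deposited, so every
pipeline stage is exercised on synthetic label maps instead.  The anatomy
phantom is a half-ellipsoid ventricular wall (myocardium) carrying a dense
scar patch, through which a viable-myocardium channel of controllable
radius, length and wall roughness is tunneled along the mid-wall surface.
The scar patch is a sleeve around the channel, so the channel is surrounded
by scar and opens into healthy myocardium at both ends — the anatomy an HT
channel is defined by.

Wall roughness emulates tissue heterogeneity (a mixture of preserved and
scarred tissue forms a structurally complex surface): the channel radius is
perturbed by seeded band-limited noise in arclength and wall angle, with
amplitude in mm.  Roughness drives the triangle count per mm of the meshed
channel and therefore the HT index.

Phantoms are label maps only — no MR intensities, noise or partial-volume
physics — because the pipeline's input is a segmentation.

Default grid: 128 x 128 x 96 voxels at 1 mm isotropic, which keeps an
end-to-end run at desk scale; a 0.5 mm hi-res variant can be requested for
slower runs closer to the ex-vivo acquisition scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .volume import BinaryMask, LabelCodes, LabelVolume

__all__ = [
    "ChannelSpec",
    "ShellSpec",
    "ScarSpec",
    "SpeckSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_cylinder_mask",
    "make_torus_mask",
    "make_sphere_mask",
    "make_ventricle_phantom",
    "preset_spec",
    "PRESETS",
]


def _voxel_centers(shape, spacing, origin=(0.0, 0.0, 0.0)):
    axes = [origin[d] + np.arange(shape[d]) * spacing[d] for d in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def make_cylinder_mask(
    radius_mm: float,
    length_mm: float,
    spacing_mm: float | tuple[float, float, float] = 1.0,
    axis: int = 2,
    pad_voxels: int = 3,
) -> BinaryMask:
    """Voxelized solid cylinder along a coordinate axis.

    Voxel centers within ``radius_mm`` of the axis and with axial coordinate
    in (0, length) are set; axial sampling is offset by half a voxel so the
    voxel count tracks pi r^2 L closely.
    """
    spacing = (spacing_mm,) * 3 if np.isscalar(spacing_mm) else tuple(spacing_mm)
    if radius_mm < 2 * max(spacing):
        raise ValueError(
            f"cylinder radius {radius_mm} mm is below resolution (needs >= 2x spacing)"
        )
    s_ax = spacing[axis]
    others = [d for d in range(3) if d != axis]
    n_rad = [int(np.ceil(radius_mm / spacing[d])) + pad_voxels for d in others]
    n_ax = int(round(length_mm / s_ax))
    shape = [0, 0, 0]
    shape[axis] = n_ax + 2 * pad_voxels
    shape[others[0]] = 2 * n_rad[0] + 1
    shape[others[1]] = 2 * n_rad[1] + 1
    origin = [0.0, 0.0, 0.0]
    origin[axis] = -(pad_voxels - 0.5) * s_ax
    origin[others[0]] = -n_rad[0] * spacing[others[0]]
    origin[others[1]] = -n_rad[1] * spacing[others[1]]
    xs = _voxel_centers(shape, spacing, origin)
    rad2 = xs[others[0]] ** 2 + xs[others[1]] ** 2
    grid = (rad2 <= radius_mm**2) & (xs[axis] > 0) & (xs[axis] < length_mm)
    return BinaryMask(grid, spacing, tuple(origin))


def make_torus_mask(
    major_mm: float,
    minor_mm: float,
    spacing_mm: float | tuple[float, float, float] = 1.0,
    pad_voxels: int = 3,
) -> BinaryMask:
    """Voxelized solid torus in the xy-plane (skeleton cycle-topology oracle)."""
    spacing = (spacing_mm,) * 3 if np.isscalar(spacing_mm) else tuple(spacing_mm)
    if minor_mm < 2 * max(spacing):
        raise ValueError("torus minor radius is below resolution (needs >= 2x spacing)")
    if major_mm <= minor_mm:
        raise ValueError("major radius must exceed minor radius")
    ext = major_mm + minor_mm
    n_xy = [int(np.ceil(ext / spacing[d])) + pad_voxels for d in (0, 1)]
    n_z = int(np.ceil(minor_mm / spacing[2])) + pad_voxels
    shape = (2 * n_xy[0] + 1, 2 * n_xy[1] + 1, 2 * n_z + 1)
    origin = (-n_xy[0] * spacing[0], -n_xy[1] * spacing[1], -n_z * spacing[2])
    x, y, z = _voxel_centers(shape, spacing, origin)
    grid = (np.sqrt(x**2 + y**2) - major_mm) ** 2 + z**2 <= minor_mm**2
    return BinaryMask(grid, spacing, origin)


def make_sphere_mask(
    radius_mm: float,
    spacing_mm: float | tuple[float, float, float] = 1.0,
    pad_voxels: int = 3,
) -> BinaryMask:
    """Voxelized solid ball centered at the origin."""
    spacing = (spacing_mm,) * 3 if np.isscalar(spacing_mm) else tuple(spacing_mm)
    n = [int(np.ceil(radius_mm / spacing[d])) + pad_voxels for d in range(3)]
    shape = tuple(2 * ni + 1 for ni in n)
    origin = tuple(-n[d] * spacing[d] for d in range(3))
    x, y, z = _voxel_centers(shape, spacing, origin)
    grid = x**2 + y**2 + z**2 <= radius_mm**2
    return BinaryMask(grid, spacing, origin)


@dataclass(frozen=True)
class ShellSpec:
    """Half-ellipsoid ventricular wall."""

    outer_radii_mm: tuple[float, float, float] = (45.0, 45.0, 80.0)
    wall_mm: float = 10.0


@dataclass(frozen=True)
class ScarSpec:
    """Dense scar sleeve wrapped around the channel centerline."""

    sleeve_radius_mm: float = 12.0
    present: bool = True


@dataclass(frozen=True)
class ChannelSpec:
    """Viable channel tunneled through the scar along the mid-wall."""

    radius_mm: float = 3.0
    length_mm: float = 30.0
    azimuth_deg: float = 0.0
    center_polar_deg: float = 60.0  # where on the meridian the channel sits
    roughness_amplitude_mm: float = 0.0
    roughness_wavelength_mm: float = 6.0
    roughness_seed: int = 0


@dataclass(frozen=True)
class SpeckSpec:
    """Isolated myocardium noise blobs floating in the cavity near the scar;
    radii are chosen to mesh below or above the 100-triangle cleanup filter."""

    radii_mm: tuple[float, ...] = ()
    offset_mm: float = 12.0  # inward distance from the inner wall


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shell: ShellSpec = field(default_factory=ShellSpec)
    scar: ScarSpec = field(default_factory=ScarSpec)
    channel: ChannelSpec | None = field(default_factory=ChannelSpec)
    specks: SpeckSpec = field(default_factory=SpeckSpec)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if any(s <= 0 for s in self.spacing_mm) or any(n < 8 for n in self.grid_shape):
            problems.append("grid_shape must be >= 8 per axis with positive spacing")
        if self.shell.wall_mm <= 0 or min(self.shell.outer_radii_mm) <= self.shell.wall_mm:
            problems.append("shell wall must be positive and thinner than the radii")
        if self.channel is not None:
            ch = self.channel
            if ch.radius_mm <= 0 or ch.length_mm <= 0:
                problems.append("channel radius and length must be positive")
            if ch.roughness_amplitude_mm < 0:
                problems.append("roughness amplitude must be >= 0")
            if self.scar.present and ch.radius_mm + ch.roughness_amplitude_mm >= self.scar.sleeve_radius_mm:
                problems.append("channel (radius + roughness) must fit inside the scar sleeve")
        if problems:
            raise ValueError("invalid phantom spec: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Designed geometry recorded alongside the phantom."""

    centerline_mm: np.ndarray | None  # (n, 3) polyline of the channel axis
    channel_radius_mm: float | None
    channel_length_mm: float | None
    roughness_amplitude_mm: float | None
    speck_centers_mm: list[list[float]]
    speck_radii_mm: list[float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centerline_mm": None
            if self.centerline_mm is None
            else np.round(self.centerline_mm, 6).tolist(),
            "channel_radius_mm": self.channel_radius_mm,
            "channel_length_mm": self.channel_length_mm,
            "roughness_amplitude_mm": self.roughness_amplitude_mm,
            "speck_centers_mm": self.speck_centers_mm,
            "speck_radii_mm": self.speck_radii_mm,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _meridian_centerline(spec: PhantomSpec, total_length_mm: float) -> np.ndarray:
    """Polyline along the mid-wall meridian at the channel azimuth, cut to
    ``total_length_mm`` of arc centered on the channel's polar position."""
    shell = spec.shell
    center = _shell_center(spec)
    mid = np.asarray(shell.outer_radii_mm) - shell.wall_mm / 2.0
    ch = spec.channel if spec.channel is not None else ChannelSpec()
    phi = np.deg2rad(ch.azimuth_deg)
    theta = np.linspace(np.deg2rad(5), np.pi / 2, 4000)
    pts = np.stack(
        [
            center[0] + mid[0] * np.sin(theta) * np.cos(phi),
            center[1] + mid[1] * np.sin(theta) * np.sin(phi),
            center[2] - mid[2] * np.cos(theta),
        ],
        axis=1,
    )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_center = np.interp(np.deg2rad(ch.center_polar_deg), theta, s)
    lo, hi = s_center - total_length_mm / 2, s_center + total_length_mm / 2
    if lo < 0 or hi > s[-1]:
        raise ValueError("channel does not fit on the phantom meridian")
    keep = (s >= lo) & (s <= hi)
    return pts[keep]


def _shell_center(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    return np.array(
        [nx * sx / 2.0, ny * sy / 2.0, nz * sz - spec.shell.outer_radii_mm[2] * 0.1 - 2.0]
    )


def _band_limited_noise(rng: np.random.Generator, wavelength_mm: float):
    """Seeded smooth noise field over (arclength s, wall angle psi), unit RMS."""
    n_modes = 6
    freqs = (2 * np.pi / wavelength_mm) * (0.5 + rng.random(n_modes))
    m = rng.integers(1, 5, size=n_modes)  # angular harmonics
    phases = rng.uniform(0, 2 * np.pi, size=(n_modes, 2))
    amps = rng.uniform(0.5, 1.0, n_modes)
    amps = amps / np.sqrt(0.5 * np.sum(amps**2))  # unit RMS

    def noise(s: np.ndarray, psi: np.ndarray) -> np.ndarray:
        out = np.zeros_like(s, dtype=float)
        for k in range(n_modes):
            out += amps[k] * np.cos(freqs[k] * s + phases[k, 0]) * np.cos(
                m[k] * psi + phases[k, 1]
            )
        return out

    return noise


def _transport_frames(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangents + parallel-transported normal frames along a polyline."""
    tang = np.gradient(polyline, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.zeros_like(tang)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tang[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n0 = np.cross(tang[0], ref)
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(tang)):
        v = normals[i - 1] - (normals[i - 1] @ tang[i]) * tang[i]
        normals[i] = v / max(np.linalg.norm(v), 1e-12)
    binormals = np.cross(tang, normals)
    return tang, normals, binormals


def _tube_mask(
    grid_shape,
    spacing,
    centerline: np.ndarray,
    radius_fn,
    max_radius: float,
) -> np.ndarray:
    """Voxels within radius_fn(s, psi) of the centerline (dense resampling)."""
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    dense_s = np.arange(0, s[-1], 0.25)
    dense = np.stack([np.interp(dense_s, s, centerline[:, d]) for d in range(3)], axis=1)
    _, normals, binormals = _transport_frames(dense)

    lo = np.maximum(np.floor((dense.min(axis=0) - max_radius) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((dense.max(axis=0) + max_radius) / spacing).astype(int) + 1, grid_shape
    )
    axes = [np.arange(lo[d], hi[d]) * spacing[d] for d in range(3)]
    xs = np.meshgrid(*axes, indexing="ij")
    vox = np.stack([a.ravel() for a in xs], axis=1)

    dist, nearest = cKDTree(dense).query(vox)
    cand = dist <= max_radius
    rel = vox[cand] - dense[nearest[cand]]
    nrm = normals[nearest[cand]]
    bin_ = binormals[nearest[cand]]
    psi = np.arctan2(np.einsum("ij,ij->i", rel, bin_), np.einsum("ij,ij->i", rel, nrm))
    r_eff = radius_fn(dense_s[nearest[cand]], psi)
    inside = np.zeros(len(vox), dtype=bool)
    inside[np.where(cand)[0]] = dist[cand] <= r_eff

    out = np.zeros(grid_shape, dtype=bool)
    sub = inside.reshape(tuple(hi - lo))
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return out


def make_ventricle_phantom(spec: PhantomSpec) -> tuple[LabelVolume, GroundTruth]:
    """Build the infarcted-ventricle label map and its ground truth.

    Label codes: background 0, myocardium 1, scar 2.  Channel voxels are
    always myocardium (they override scar); the scar sleeve never overwrites
    the channel.  Fully deterministic for a given spec (seeds included).
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing_mm)
    center = _shell_center(spec)
    outer = np.asarray(spec.shell.outer_radii_mm)
    inner = outer - spec.shell.wall_mm

    x, y, z = _voxel_centers(shape, spacing)
    rho_out = ((x - center[0]) / outer[0]) ** 2 + ((y - center[1]) / outer[1]) ** 2 + (
        (z - center[2]) / outer[2]
    ) ** 2
    rho_in = ((x - center[0]) / inner[0]) ** 2 + ((y - center[1]) / inner[1]) ** 2 + (
        (z - center[2]) / inner[2]
    ) ** 2
    half = z <= center[2]
    shell = (rho_out <= 1.0) & (rho_in >= 1.0) & half
    cavity = (rho_in < 1.0) & half

    grid = np.zeros(shape, dtype=np.int32)
    grid[shell] = 1  # myocardium

    ch = spec.channel
    gt_centerline = None
    gt_length = None
    scar_mask = np.zeros(shape, dtype=bool)
    channel_mask = np.zeros(shape, dtype=bool)

    if spec.scar.present:
        sleeve_r = spec.scar.sleeve_radius_mm
        base_len = ch.length_mm if ch is not None else 30.0
        # the channel pierces the sleeve's end caps and opens into healthy wall
        ext = sleeve_r + 4.0
        full_line = _meridian_centerline(spec, base_len + 2 * ext)
        seg = np.linalg.norm(np.diff(full_line, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        mid = (s >= ext) & (s <= s[-1] - ext)
        scar_line = full_line[mid]
        scar_mask = _tube_mask(shape, spacing, scar_line,
                               lambda ss, psi: np.full_like(ss, sleeve_r), sleeve_r)
        scar_mask &= shell
        grid[scar_mask] = 2  # scar

        if ch is not None:
            if ch.roughness_amplitude_mm > 0:
                noise = _band_limited_noise(
                    np.random.default_rng(ch.roughness_seed), ch.roughness_wavelength_mm
                )
                radius_fn = lambda ss, psi: np.maximum(
                    ch.radius_mm + ch.roughness_amplitude_mm * noise(ss, psi), 1.5
                )
            else:
                radius_fn = lambda ss, psi: np.full_like(ss, ch.radius_mm)
            max_r = ch.radius_mm + 3 * ch.roughness_amplitude_mm + 0.5
            channel_mask = _tube_mask(shape, spacing, full_line, radius_fn, max_r)
            channel_mask &= shell  # the tunnel stays within the wall
            grid[channel_mask] = 1  # viable channel overrides scar
            gt_centerline = scar_line
            gt_length = float(s[mid][-1] - s[mid][0])

    speck_centers, speck_radii = [], []
    if spec.specks.radii_mm:
        # floating in the cavity, inward of the channel center, spaced apart
        anchor = _meridian_centerline(spec, 1.0).mean(axis=0)
        inward = center + np.array([0, 0, 10.0]) - anchor
        inward = inward / np.linalg.norm(inward)
        for k, r in enumerate(spec.specks.radii_mm):
            c = anchor + inward * (spec.specks.offset_mm + 12.0 * k)
            d2 = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r**2
            if (grid[d2] != 0).any() or not cavity[d2].all():
                raise ValueError(f"speck {k} does not fit isolated in the cavity")
            grid[d2] = 1
            speck_centers.append([float(v) for v in c])
            speck_radii.append(float(r))

    vol = LabelVolume(grid, spacing, (0.0, 0.0, 0.0), LabelCodes(0, 1, 2))
    gt = GroundTruth(
        centerline_mm=gt_centerline,
        channel_radius_mm=None if ch is None else ch.radius_mm,
        channel_length_mm=gt_length if ch is not None else None,
        roughness_amplitude_mm=None if ch is None else ch.roughness_amplitude_mm,
        speck_centers_mm=speck_centers,
        speck_radii_mm=speck_radii,
    )
    return vol, gt


#: named fixture suite used throughout the tests and the CLI
PRESETS: dict[str, PhantomSpec] = {
    "smooth-channel": PhantomSpec(channel=ChannelSpec(radius_mm=3.0, length_mm=30.0)),
    "rough-channel": PhantomSpec(
        channel=ChannelSpec(
            radius_mm=3.0, length_mm=30.0, roughness_amplitude_mm=1.2, roughness_seed=11
        )
    ),
    "thick-tube": PhantomSpec(
        shell=ShellSpec(wall_mm=18.0),
        scar=ScarSpec(sleeve_radius_mm=16.0),
        channel=ChannelSpec(radius_mm=8.0, length_mm=30.0),
    ),
    "no-channel": PhantomSpec(channel=None),
    "specks": PhantomSpec(
        channel=ChannelSpec(radius_mm=3.0, length_mm=30.0),
        specks=SpeckSpec(radii_mm=(1.4, 3.5)),
    ),
}


def preset_spec(name: str, seed: int | None = None) -> PhantomSpec:
    """Look up a named phantom preset, optionally re-seeding its roughness."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None and spec.channel is not None:
        spec = replace(spec, channel=replace(spec.channel, roughness_seed=seed), seed=seed)
    elif seed is not None:
        spec = replace(spec, seed=seed)
    return spec
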