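"""Synthetic two-channel z-stacks and FRAP traces with known ground truth.

The stack generator emulates the imaging situation the pipeline is built
for: a single bright, irregularly shaped cell filling much of the field,
with dark intracellular vacuoles, a brighter rim at the cell edge, diffuse
cytoplasmic background, and 1-3 µm irregular puncta planted in one or both
channels.  A controllable fraction ``coincident_fraction`` of red puncta is
planted exactly on top of a green punctum (true overlap 1); the rest are
placed with no cross-channel contact (true overlap 0).  Puncta are rendered
as thresholded anisotropic Gaussians with random in-plane elongation and
rotation, so their supports are compact but irregular; a light Gaussian blur
stands in for the microscope PSF, and noise is Poisson on the signal plus
Gaussian read noise.

The FRAP generator produces single-exponential recoveries with a known
mobile fraction and time constant, multiplicative acquisition bleaching
applied to bleach and reference ROIs alike, an additive background, and
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .stack_model import CellMask, FrapTrace, TwoChannelStack

# support cutoff for the thresholded Gaussian rendering: the planted support
# is {g > exp(-2)}, i.e. the 2-sigma ellipsoid, so "diameter" below means
# the 4-sigma full width of the support
_SUPPORT_CUTOFF = np.exp(-2.0)


@dataclass
class SceneParams:
    """Scene parameters for :func:`generate_stack` (pixel units unless noted).

    Defaults describe a single multiciliated-cell-like field: a ~21 µm cell
    in a 25.6 µm field at 0.1 µm/px, 20 optical sections 0.5 µm apart, foci
    of 1-3 µm diameter, ~3:1 cell:background contrast and a brighter rim.
    """

    shape: tuple[int, int, int] = (20, 256, 256)
    pixel_size_xy: float = 0.1  # µm/px
    z_step: float = 0.5  # µm/layer
    cell_radius: float = 105.0
    cell_irregularity: float = 0.08  # radial Fourier perturbation amplitude
    background_level: float = 12.0
    cell_level: float = 100.0
    rim_extra: float = 80.0
    rim_width: float = 3.0
    n_vacuoles: int = 2
    vacuole_radius: tuple[float, float] = (8.0, 14.0)
    vacuole_level: float = 20.0
    n_puncta_green: int = 8
    n_puncta_red: int = 8
    coincident_fraction: float = 0.5
    punctum_diameter_um: tuple[float, float] = (1.0, 3.0)
    punctum_amplitude: float = 150.0
    punctum_edge_margin: float = 30.0  # min centroid clearance beyond support radius
    min_separation: int = 8  # in-plane support gap (px) between distinct puncta
    psf_sigma: float = 1.0  # in-plane blur, px
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    max_placement_attempts: int = 2000


@dataclass
class PlantedPunctum:
    channel: str
    punctum_id: int
    centroid_zyx: tuple[float, float, float]
    voxels: np.ndarray  # (n, 3) int (z, y, x)
    volume: int
    amplitude: float
    paired_with: int | None  # id of the coincident other-channel punctum
    true_overlap: float


@dataclass
class SceneGroundTruth:
    cell_mask: CellMask
    puncta: list[PlantedPunctum]
    params: SceneParams
    seed: int

    def by_channel(self, channel: str) -> list[PlantedPunctum]:
        return [p for p in self.puncta if p.channel == channel]


# ---------------------------------------------------------------------------
# stack generation
# ---------------------------------------------------------------------------

def _cell_footprint(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Irregular 2D blob: radius perturbed by low-order Fourier modes."""
    _, ny, nx = params.shape
    cy, cx = ny / 2.0, nx / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(yy - cy, xx - cx)
    radius = np.full_like(theta, params.cell_radius)
    for k in range(2, 6):
        amp = params.cell_irregularity * params.cell_radius * rng.uniform(0.3, 1.0) / (k - 1)
        phase = rng.uniform(0, 2 * np.pi)
        radius = radius + amp * np.cos(k * theta + phase)
    return r <= radius


def _cell_mask_3d(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Per-layer cell cross sections: base footprint, tapered at the z extremes."""
    nz = params.shape[0]
    base = _cell_footprint(params, rng)
    zc = (nz - 1) / 2.0
    layers = np.zeros(params.shape, dtype=bool)
    for z in range(nz):
        erosion = int(round(6.0 * ((z - zc) / max(zc, 1.0)) ** 2))
        if erosion > 0:
            layers[z] = ndi.binary_erosion(base, iterations=erosion)
        else:
            layers[z] = base
    return layers


def _render_punctum(
    params: SceneParams, rng: np.random.Generator, cell: np.ndarray
):
    """Draw one punctum's shape; returns (offsets (n,3), gauss values (n,))."""
    nz, ny, nx = params.shape
    d_um = rng.uniform(*params.punctum_diameter_um)
    d_px = d_um / params.pixel_size_xy
    # support full width = 4 sigma; random in-plane elongation and rotation
    s_base = d_px / 4.0
    elong = rng.uniform(0.7, 1.4)
    sy, sx = s_base * elong, s_base / elong
    sz = (d_um / params.z_step) / 4.0
    phi = rng.uniform(0, np.pi)
    # evaluate the rotated anisotropic Gaussian on a local grid
    half_xy = int(np.ceil(2.0 * max(sy, sx))) + 1
    half_z = max(int(np.ceil(2.0 * sz)), 0)
    zz, yy, xx = np.mgrid[-half_z:half_z + 1, -half_xy:half_xy + 1,
                          -half_xy:half_xy + 1]
    u = xx * np.cos(phi) + yy * np.sin(phi)
    v = -xx * np.sin(phi) + yy * np.cos(phi)
    g = np.exp(
        -0.5 * (u ** 2 / sx ** 2 + v ** 2 / sy ** 2
                + zz ** 2 / max(sz, 0.25) ** 2)
    )
    inside = g > _SUPPORT_CUTOFF
    offsets = np.column_stack([zz[inside], yy[inside], xx[inside]])
    return offsets, g[inside]


def _feasible(vox: np.ndarray, allowed: np.ndarray) -> bool:
    nz, ny, nx = allowed.shape
    if (vox < 0).any():
        return False
    if (vox[:, 0] >= nz).any() or (vox[:, 1] >= ny).any() or (vox[:, 2] >= nx).any():
        return False
    return bool(allowed[vox[:, 0], vox[:, 1], vox[:, 2]].all())


def generate_stack(
    params: SceneParams | None = None, seed: int = 0
) -> tuple[TwoChannelStack, SceneGroundTruth]:
    """Render a synthetic two-channel stack with known planted ground truth.

    Deterministic per seed.  Raises if the requested puncta cannot be packed
    into the cell within the placement-attempt budget.
    """
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(seed)
    nz, ny, nx = params.shape

    cell = _cell_mask_3d(params, rng)

    # vacuoles: dark ellipsoids spanning a few layers, kept off the rim
    vacuole = np.zeros(params.shape, dtype=bool)
    interior = ndi.binary_erosion(
        cell, structure=np.ones((1, 3, 3), dtype=bool),
        iterations=int(max(params.vacuole_radius) + 8),
    )
    for _ in range(params.n_vacuoles):
        for _attempt in range(params.max_placement_attempts):
            z0 = rng.integers(2, nz - 2)
            ys, xs = np.nonzero(interior[z0])
            if ys.size == 0:
                continue
            k = rng.integers(ys.size)
            y0, x0 = int(ys[k]), int(xs[k])
            rv = rng.uniform(*params.vacuole_radius)
            zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
            ell = ((zz - z0) / 1.5) ** 2 + ((yy - y0) / rv) ** 2 + (
                (xx - x0) / rv) ** 2 <= 1.0
            vacuole |= ell & cell
            break

    # puncta placement: supports must stay well clear of the cell edge (the
    # pipeline attenuates edge signal), of vacuoles, and of same- and
    # other-channel puncta unless deliberately coincident
    edge_dist = np.zeros(params.shape)
    for z in range(nz):
        if cell[z].any():
            edge_dist[z] = ndi.distance_transform_edt(cell[z])
    forbidden_pad = ndi.binary_dilation(
        vacuole, structure=np.ones((3, 5, 5), dtype=bool)
    )

    n_pairs = int(round(params.coincident_fraction * params.n_puncta_red))
    if n_pairs > params.n_puncta_green:
        raise ValueError("coincident_fraction requires more green puncta")

    occupancy = np.zeros(params.shape, dtype=bool)  # all planted supports
    planted: list[PlantedPunctum] = []
    next_id = 1

    def place(channel: str, pid: int) -> PlantedPunctum:
        nonlocal occupancy
        for _attempt in range(params.max_placement_attempts):
            offsets, g = _render_punctum(params, rng, cell)
            r_support = float(np.abs(offsets[:, 1:]).max())
            clearance = params.punctum_edge_margin + r_support
            half_z = int(np.abs(offsets[:, 0]).max())
            zc = int(rng.integers(half_z + 1, nz - half_z - 1))
            ok = edge_dist[zc] >= clearance
            ys, xs = np.nonzero(ok)
            if ys.size == 0:
                continue
            k = rng.integers(ys.size)
            vox = offsets + np.array([zc, int(ys[k]), int(xs[k])])
            if not _feasible(vox, cell & ~forbidden_pad):
                continue
            # keep supports well separated (also across z) so the planted
            # scene contains resolvable, distinct organelles: the PSF halo of
            # one punctum must not bridge into a neighbour's basin
            if occupancy[vox[:, 0], vox[:, 1], vox[:, 2]].any():
                continue
            # dilate the support within a local crop only (the full-volume
            # dilation dominates runtime otherwise)
            m = params.min_separation
            lo = np.maximum(vox.min(axis=0) - np.array([1, m, m]), 0)
            hi = np.minimum(vox.max(axis=0) + np.array([1, m, m]) + 1,
                            np.array([nz, ny, nx]))
            local = np.zeros(tuple(hi - lo), dtype=bool)
            lv = vox - lo
            local[lv[:, 0], lv[:, 1], lv[:, 2]] = True
            local = ndi.binary_dilation(
                local, structure=np.ones((3, 2 * m + 1, 2 * m + 1), bool)
            )
            window = occupancy[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            if (local & window).any():
                continue
            window |= local
            centroid = tuple(vox.mean(axis=0))
            return PlantedPunctum(
                channel=channel, punctum_id=pid, centroid_zyx=centroid,
                voxels=vox, volume=int(vox.shape[0]),
                amplitude=params.punctum_amplitude, paired_with=None,
                true_overlap=0.0,
            ), g
        raise RuntimeError(
            f"puncta do not fit in cell: placement failed for {channel} "
            f"punctum after {params.max_placement_attempts} attempts"
        )

    green_img = np.zeros(params.shape)
    red_img = np.zeros(params.shape)

    greens: list[tuple[PlantedPunctum, np.ndarray]] = []
    for i in range(params.n_puncta_green):
        p, g = place("green", next_id)
        next_id += 1
        greens.append((p, g))
        green_img[p.voxels[:, 0], p.voxels[:, 1], p.voxels[:, 2]] += (
            params.punctum_amplitude * g
        )
        planted.append(p)

    # coincident red puncta reuse the first n_pairs green supports exactly
    for i in range(params.n_puncta_red):
        if i < n_pairs:
            gp, g = greens[i]
            p = PlantedPunctum(
                channel="red", punctum_id=next_id,
                centroid_zyx=gp.centroid_zyx, voxels=gp.voxels.copy(),
                volume=gp.volume, amplitude=params.punctum_amplitude,
                paired_with=gp.punctum_id, true_overlap=1.0,
            )
            gp.paired_with = p.punctum_id
            gp.true_overlap = 1.0
        else:
            p, g = place("red", next_id)
        next_id += 1
        red_img[p.voxels[:, 0], p.voxels[:, 1], p.voxels[:, 2]] += (
            params.punctum_amplitude * g
        )
        planted.append(p)

    # assemble the scene for both channels
    def compose(puncta_img: np.ndarray) -> np.ndarray:
        img = np.full(params.shape, params.background_level)
        img[cell] = params.cell_level
        rim = cell & (edge_dist <= params.rim_width)
        img[rim] += params.rim_extra
        img[vacuole] = params.vacuole_level
        img += puncta_img
        if params.psf_sigma > 0:
            for z in range(nz):
                img[z] = ndi.gaussian_filter(img[z], params.psf_sigma)
        if params.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if params.read_noise_sd > 0:
            img = img + rng.normal(0, params.read_noise_sd, img.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    stack = TwoChannelStack(
        green=compose(green_img),
        red=compose(red_img),
        pixel_size_xy=params.pixel_size_xy,
        z_step=params.z_step,
        source_id=f"synthetic(seed={seed})",
    )
    truth = SceneGroundTruth(
        cell_mask=CellMask(layers=cell), puncta=planted, params=params,
        seed=seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP trace generation
# ---------------------------------------------------------------------------

@dataclass
class FrapParams:
    """Parameters for :func:`generate_frap_trace`.

    Defaults emulate the acquisition cadence of a point-scanning confocal
    FRAP experiment: 300 frames at 0.2 s spacing, 10 of them pre-bleach.
    """

    n_prebleach: int = 10
    n_postbleach: int = 290
    dt: float = 0.2  # s/frame
    mobile_fraction: float = 60.0  # percent
    tau: float = 3.0  # s
    bleach_depth: float = 0.2  # normalized post-bleach floor f0
    acq_bleach_rate: float = 0.002  # multiplicative loss per frame
    bleach_scale: float = 900.0  # raw counts at pre-bleach level
    reference_scale: float = 1200.0
    background_level: float = 60.0
    noise_frac: float = 0.02  # relative Gaussian noise on each ROI


def generate_frap_trace(
    params: FrapParams | None = None, seed: int = 0
) -> tuple[FrapTrace, dict]:
    """Simulate one FRAP experiment; returns (trace, ground truth dict).

    The underlying recovery is single-exponential with plateau
    f_inf = f0 + (mobile/100) * (1 - f0); acquisition bleaching multiplies
    bleach and reference ROIs alike by (1 - acq_bleach_rate)^frame, the
    background is additive, and each ROI gets independent Gaussian noise.
    Deterministic per seed.
    """
    if params is None:
        params = FrapParams()
    rng = np.random.default_rng(seed)
    n = params.n_prebleach + params.n_postbleach
    times = np.arange(n) * params.dt
    f = np.ones(n)
    f0 = params.bleach_depth
    f_inf = f0 + (params.mobile_fraction / 100.0) * (1.0 - f0)
    t_post = times[params.n_prebleach:] - times[params.n_prebleach]
    f[params.n_prebleach:] = f0 + (f_inf - f0) * (1.0 - np.exp(-t_post / params.tau))

    decay = (1.0 - params.acq_bleach_rate) ** np.arange(n)
    bleach = params.bleach_scale * f * decay
    reference = params.reference_scale * decay
    background = np.full(n, params.background_level)

    if params.noise_frac > 0:
        bleach = bleach * (1 + rng.normal(0, params.noise_frac, n))
        reference = reference * (1 + rng.normal(0, params.noise_frac, n))
        background = background + rng.normal(
            0, params.noise_frac * params.background_level, n
        )

    trace = FrapTrace(
        times=times,
        bleach_roi=bleach + background,
        reference_roi=reference + background,
        background_roi=background,
        n_prebleach=params.n_prebleach,
        label=f"synthetic(seed={seed})",
    )
    truth = {
        "mobile_fraction": params.mobile_fraction,
        "tau": params.tau,
        "f0": f0,
        "f_inf": f_inf,
    }
    return trace, truth
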