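"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates 3D STED Q-FISH acquisitions of telomeres in
single nuclei: sparse, bright, diffraction-limited-to-sub-diffraction
anisotropic Gaussian spots with lognormally distributed amplitudes on
a low Poisson photon-count background, confined to an ellipsoidal
nuclear volume.  Defaults reproduce the imaging scale of the real
experiments: 30 x 30 x 200 nm voxels, lateral spot sigma 56 nm (FWHM
~132 nm), axial sigma 170 nm (FWHM ~400 nm, the axial resolution
floor), background 2 photon counts and lognormal peak amplitudes with
geometric mean 50 counts.  Noise is pure Poisson on the expected
photon counts (photon-counting detection; no read noise), and spot
shapes are separable Gaussians without STED side-lobe structure — the
downstream analysis model is Gaussian, so additional optical fidelity
would add nothing testable.

Every generator is seed-deterministic and returns machine-readable
ground truth next to the rendered images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import ImageStack3D, NucleusMask, VoxelGeometry

__all__ = [
    "SpotGroundTruth",
    "SimulationConfig",
    "CellSimulation",
    "simulate_nucleus_stack",
    "simulate_cell_cycle_experiment",
    "simulate_origami_field",
    "simulate_trf_lane",
    "simulate_nested_values",
]


@dataclass
class SpotGroundTruth:
    """True parameters of one rendered spot.

    ``true_integrated_counts`` is the lateral 2D integral of the spot's
    center plane in counts times pixel area, i.e. the quantity the
    profile-fit integral ``2*pi*b*d_x*d_y`` estimates.
    """

    true_center_nm: tuple[float, float, float]  # (z, y, x)
    true_peak_counts: float
    true_sigma_nm: tuple[float, float]  # (lateral, axial)
    true_integrated_counts: float


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated single-nucleus acquisition.

    ``min_separation_nm`` is the minimum lateral center distance; axial
    distances count scaled down by ``axial_separation_scale`` (the
    axial/lateral resolution ratio), i.e. placement enforces
    ``sqrt(dx^2 + dy^2 + (dz/scale)^2) >= min_separation_nm``.
    """

    n_spots: int = 90
    nucleus_semiaxes_nm: tuple[float, float, float] = (1900.0, 3300.0, 3300.0)  # (z, y, x)
    amplitude_geo_mean: float = 50.0
    amplitude_geo_sd: float = 1.5
    sigma_xy_nm: float = 56.0
    sigma_z_nm: float = 170.0
    background_counts: float = 2.0
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    shape: tuple[int, int, int] = (21, 256, 256)  # (z, y, x)
    min_separation_nm: float = 400.0
    axial_separation_scale: float = 3.0
    poisson_noise: bool = True
    seed: int = 0


@dataclass
class CellSimulation:
    """One simulated cell: rendered stack plus ground truth."""

    cell_id: str
    phase: str
    stack: ImageStack3D
    truths: list[SpotGroundTruth]
    mask: NucleusMask


def _place_spots(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample spot centers (nm, (z, y, x)) inside the nuclear
    ellipsoid with the anisotropic minimum-separation constraint."""
    scale = config.geometry.scale_nm()
    center = 0.5 * (np.array(config.shape) - 1) * scale
    semi = np.array(config.nucleus_semiaxes_nm, dtype=float)
    sep2 = config.min_separation_nm**2
    ax = config.axial_separation_scale
    placed: list[np.ndarray] = []
    for _ in range(config.n_spots):
        for attempt in range(10_000):
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u**2) > 1.0:
                continue
            pos = center + u * semi
            ok = True
            for q in placed:
                d = pos - q
                if d[1] ** 2 + d[2] ** 2 + (d[0] / ax) ** 2 < sep2:
                    ok = False
                    break
            if ok:
                placed.append(pos)
                break
        else:
            raise RuntimeError(
                "spot placement failed; reduce n_spots or min_separation_nm"
            )
    return np.array(placed) if placed else np.empty((0, 3))


def _render(
    shape: tuple[int, int, int],
    geometry: VoxelGeometry,
    centers_nm: np.ndarray,
    amplitudes: np.ndarray,
    sigma_xy_nm: float,
    sigma_z_nm: float,
    background: float,
) -> np.ndarray:
    """Expected photon counts: constant background plus separable
    anisotropic Gaussians, each rendered on a +/-4 sigma local patch."""
    lam = np.full(shape, float(background))
    scale = geometry.scale_nm()
    sig_vox = np.array([sigma_z_nm, sigma_xy_nm, sigma_xy_nm]) / scale
    for pos_nm, amp in zip(centers_nm, amplitudes):
        c = pos_nm / scale  # fractional voxel index
        lo = np.maximum(np.floor(c - 4 * sig_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c + 4 * sig_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz = np.arange(lo[0], hi[0])
        yy = np.arange(lo[1], hi[1])
        xx = np.arange(lo[2], hi[2])
        gz = np.exp(-0.5 * ((zz - c[0]) / sig_vox[0]) ** 2)
        gy = np.exp(-0.5 * ((yy - c[1]) / sig_vox[1]) ** 2)
        gx = np.exp(-0.5 * ((xx - c[2]) / sig_vox[2]) ** 2)
        lam[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
            amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    return lam


def _lateral_ellipse_polygon(config: SimulationConfig, margin_px: float = 3.0) -> np.ndarray:
    """64-gon around the nucleus cross-section, in pixel coordinates."""
    scale = config.geometry.scale_nm()
    cy = 0.5 * (config.shape[1] - 1)
    cx = 0.5 * (config.shape[2] - 1)
    ry = config.nucleus_semiaxes_nm[1] / scale[1] + margin_px
    rx = config.nucleus_semiaxes_nm[2] / scale[2] + margin_px
    t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    xs = np.clip(cx + rx * np.cos(t), 0, config.shape[2] - 1)
    ys = np.clip(cy + ry * np.sin(t), 0, config.shape[1] - 1)
    return np.column_stack([xs, ys])


def _integrated_counts(amp: float, sigma_xy_nm: float, geometry: VoxelGeometry) -> float:
    return float(
        2.0 * math.pi * amp * (sigma_xy_nm / geometry.dx_nm) * (sigma_xy_nm / geometry.dy_nm)
    )


def simulate_nucleus_stack(
    config: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[ImageStack3D, list[SpotGroundTruth], NucleusMask]:
    """Render one nucleus: spots inside the ellipsoid, Poisson-sampled
    photon counts, and the matching polygon mask."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    centers = _place_spots(config, rng)
    amps = config.amplitude_geo_mean * np.exp(
        rng.standard_normal(len(centers)) * math.log(config.amplitude_geo_sd)
    )
    lam = _render(
        config.shape,
        config.geometry,
        centers,
        amps,
        config.sigma_xy_nm,
        config.sigma_z_nm,
        config.background_counts,
    )
    if config.poisson_noise:
        voxels = rng.poisson(lam).astype(np.int64)
    else:
        voxels = np.rint(lam).astype(np.int64)
    stack = ImageStack3D(voxels, config.geometry, "TelC-FISH")
    truths = [
        SpotGroundTruth(
            true_center_nm=tuple(c),
            true_peak_counts=float(a),
            true_sigma_nm=(config.sigma_xy_nm, config.sigma_z_nm),
            true_integrated_counts=_integrated_counts(a, config.sigma_xy_nm, config.geometry),
        )
        for c, a in zip(centers, amps)
    ]
    return stack, truths, NucleusMask(_lateral_ellipse_polygon(config))


def simulate_cell_cycle_experiment(
    n_cells_a: int = 9,
    n_cells_b: int = 8,
    spots_a: int = 90,
    spots_b: int = 207,
    density_effect_pct: float = 0.0,
    seed: int = 0,
    count_cv: float = 0.09,
    between_cell_geo_sd: float = 1.1,
    base_config: SimulationConfig = SimulationConfig(),
    phase_a: str = "interphase",
    phase_b: str = "M-phase",
) -> list[CellSimulation]:
    """Simulate a two-condition cell-cycle experiment.

    Condition A mimics interphase nuclei (~90 telomeres), condition B
    M-phase cells (~207 telomeres, count doubling plus hypertriploid
    karyotype).  Per-cell spot counts are Normal(spots, cv 9%) rounded;
    per-cell amplitude factors are lognormal (between-cell geometric SD
    1.1); condition B amplitudes are additionally scaled by
    ``1 - density_effect_pct/100`` at unchanged spot sigma — a reduced
    brightness/density at constant size, the M-phase phenotype.
    """
    rng = np.random.default_rng(seed)
    cells: list[CellSimulation] = []
    plan = [(phase_a, n_cells_a, spots_a, 1.0), (phase_b, n_cells_b, spots_b, 1.0 - density_effect_pct / 100.0)]
    for phase, n_cells, spots, effect in plan:
        for i in range(n_cells):
            n = max(1, int(round(rng.normal(spots, count_cv * spots))))
            cell_factor = math.exp(rng.standard_normal() * math.log(between_cell_geo_sd))
            cfg = replace(
                base_config,
                n_spots=n,
                amplitude_geo_mean=base_config.amplitude_geo_mean * cell_factor * effect,
            )
            stack, truths, mask = simulate_nucleus_stack(cfg, rng)
            cells.append(
                CellSimulation(
                    cell_id=f"{phase}_{i:02d}", phase=phase, stack=stack, truths=truths, mask=mask
                )
            )
    return cells


def simulate_origami_field(
    n_beads: int = 100,
    n_fluorophores: int = 34,
    counts_per_fluorophore: float = 60.0,
    cv: float = 0.1,
    geometry: Optional[VoxelGeometry] = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (11, 512, 512),
    sigma_xy_nm: float = 56.0,
    sigma_z_nm: float = 170.0,
    background_counts: float = 1.0,
    grid_pitch_px: int = 24,
    poisson_noise: bool = True,
) -> tuple[ImageStack3D, list[SpotGroundTruth]]:
    """Render a field of isolated origami brightness standards.

    Beads sit on a jittered lateral grid (guaranteed isolation) at the
    central plane exactly — origami standards are immobilized as a
    monolayer on the coverslip, so the focus sits on the bead plane.
    Each bead's integrated brightness is
    Normal(n_fluorophores * counts_per_fluorophore, cv) and its peak
    amplitude follows from the lateral Gaussian integral.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    geometry = geometry or VoxelGeometry()
    rng = np.random.default_rng(seed)
    margin = 12
    ys = np.arange(margin, shape[1] - margin, grid_pitch_px)
    xs = np.arange(margin, shape[2] - margin, grid_pitch_px)
    capacity = len(ys) * len(xs)
    if n_beads > capacity:
        raise ValueError(f"grid holds at most {capacity} beads at this pitch")
    sites = [(y, x) for y in ys for x in xs]
    idx = rng.choice(capacity, size=n_beads, replace=False)
    scale = geometry.scale_nm()
    zc = 0.5 * (shape[0] - 1)
    centers = []
    for k in idx:
        y, x = sites[k]
        jit = rng.uniform(-0.45, 0.45, size=2) * grid_pitch_px / 3.0
        centers.append((zc * scale[0], (y + jit[0]) * scale[1], (x + jit[1]) * scale[2]))
    centers = np.array(centers)
    target = n_fluorophores * counts_per_fluorophore
    integrated = target * (1.0 + cv * rng.standard_normal(n_beads)) if cv > 0 else np.full(n_beads, target)
    integrated = np.clip(integrated, 0.05 * target, None)
    px_area = (sigma_xy_nm / geometry.dx_nm) * (sigma_xy_nm / geometry.dy_nm)
    amps = integrated / (2.0 * math.pi * px_area)
    lam = _render(shape, geometry, centers, amps, sigma_xy_nm, sigma_z_nm, background_counts)
    voxels = rng.poisson(lam).astype(np.int64) if poisson_noise else np.rint(lam).astype(np.int64)
    stack = ImageStack3D(voxels, geometry, f"origami-{n_fluorophores}")
    truths = [
        SpotGroundTruth(
            true_center_nm=tuple(c),
            true_peak_counts=float(a),
            true_sigma_nm=(sigma_xy_nm, sigma_z_nm),
            true_integrated_counts=float(i),
        )
        for c, a, i in zip(centers, amps, integrated)
    ]
    return stack, truths


#: wide molecular-weight ladder (kb) spanning the telomere smear range
DEFAULT_LADDER_KB = (48.5, 24.8, 17.1, 11.2, 8.6, 6.1, 4.2, 2.7, 1.9, 1.0, 0.7)


def simulate_trf_lane(
    mean_kb: float = 18.9,
    spread_geo_sd: float = 1.3,
    n_positions: int = 200,
    ladder_kb: Sequence[float] = DEFAULT_LADDER_KB,
    n_fragments: int = 20_000,
    seed: int = 0,
) -> dict:
    """Simulate a TRF smear with known mean fragment length.

    Fragment lengths are lognormal with arithmetic mean ``mean_kb``
    (``spread_geo_sd -> 1`` collapses to a sharp band).  Densitometry
    intensity is mass-weighted (a fragment contributes proportionally
    to its length), binned onto a migration axis through the inverse
    log-linear ladder model.  The returned ``true_mtl_kb`` is the
    number-weighted mean of the sampled fragments — exactly what the
    intensity formula recovers in the dense-sampling limit.  Fragments
    outside the ladder range are dropped from both the lane and the
    truth.
    """
    rng = np.random.default_rng(seed)
    ladder_kb = np.asarray(ladder_kb, dtype=float)
    # log-linear migration model: position grows as log10(MW) falls
    pos_of_mw = lambda mw: 100.0 * (np.log10(ladder_kb.max() * 1.2) - np.log10(mw))
    ladder_positions = pos_of_mw(ladder_kb)
    s = math.log(spread_geo_sd) if spread_geo_sd > 1.0 else 0.0
    if s > 0:
        mu = math.log(mean_kb) - 0.5 * s * s  # arithmetic mean = mean_kb
        lengths = np.exp(mu + s * rng.standard_normal(n_fragments))
    else:
        lengths = np.full(n_fragments, float(mean_kb))
    keep = (lengths >= ladder_kb.min()) & (lengths <= ladder_kb.max())
    lengths = lengths[keep]
    if lengths.size == 0:
        raise ValueError("mean_kb/spread place all fragments outside the ladder range")
    true_mtl = float(lengths.mean())
    positions = np.linspace(ladder_positions.min(), ladder_positions.max(), n_positions)
    edges = np.concatenate(
        [
            [positions[0] - 0.5 * (positions[1] - positions[0])],
            0.5 * (positions[1:] + positions[:-1]),
            [positions[-1] + 0.5 * (positions[-1] - positions[-2])],
        ]
    )
    frag_pos = pos_of_mw(lengths)
    intensities, _ = np.histogram(frag_pos, bins=edges, weights=lengths)
    return {
        "positions": positions,
        "intensities": intensities.astype(float),
        "ladder_positions": ladder_positions,
        "ladder_mw_kb": ladder_kb,
        "true_mtl_kb": true_mtl,
    }


def simulate_nested_values(
    n_cells_a: int = 9,
    n_cells_b: int = 8,
    n_per_cell: int = 90,
    geo_mean: float = 50.0,
    within_geo_sd: float = 1.5,
    between_geo_sd: float = 1.1,
    effect_pct: float = 0.0,
    seed: int = 0,
) -> dict[str, list[np.ndarray]]:
    """Lognormal per-cell value lists for two conditions (no imaging).

    A lightweight companion to :func:`simulate_cell_cycle_experiment`
    for statistics-only studies: condition "B" geometric means are
    scaled by ``1 - effect_pct/100``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[np.ndarray]] = {"A": [], "B": []}
    for label, n_cells, effect in (
        ("A", n_cells_a, 1.0),
        ("B", n_cells_b, 1.0 - effect_pct / 100.0),
    ):
        for _ in range(n_cells):
            cell_gm = geo_mean * effect * math.exp(rng.standard_normal() * math.log(between_geo_sd))
            vals = cell_gm * np.exp(rng.standard_normal(n_per_cell) * math.log(within_geo_sd))
            out[label].append(vals)
    return out
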