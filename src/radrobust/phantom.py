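"""Synthetic tumor phantoms and simulated observer segmentations.

The study design this module emulates: per tumor, one CT-like intensity
volume with a ground-truth lesion mask, five independent "manual" observer
masks, and six "semi-automatic" masks (three observers, each running a
seeded GrowCut segmentation twice). The generator's default observer
settings encode the qualitative structure the analysis probes: manual
inter-observer boundary variability is larger than semi-automatic
run-to-run variability, and repeated runs by the same semi-automatic
observer vary least.

Phantoms are spheres with randomly placed Gaussian surface spiculations,
a soft-tissue core on a lung-like background, and spatially correlated
interior texture (Gaussian-filtered white noise) so that texture features
vary across tumors. Manual observers are modeled as a smoothed random
displacement of the truth boundary — a smooth correlated field added to
the signed distance transform — plus a per-observer systematic
dilation/erosion bias and extra contour smoothing (hand contours smooth
out fine surface detail). Semi-automatic observers draw random foreground
strokes well inside the lesion and background strokes on a shell around
it, then run GrowCut.

Every output is a pure function of its seed(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import growcut
from .core import ImageVolume, SegMask

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "PhantomRanges",
    "StudyConfig",
    "SegRecord",
    "TumorCase",
    "StudyDataset",
    "generate_phantom",
    "smooth_mask",
    "simulate_manual_mask",
    "simulate_semiauto_mask",
    "generate_study",
]

_SPICULE_ANGULAR_WIDTH = 0.35  # rad; angular half-width of a surface spicule


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tumor. Spacing/shape are (z, y, x)."""

    grid_shape: tuple[int, int, int] = (28, 44, 44)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    lesion_radius: float = 8.0  # mm
    spiculation_count: int = 8
    spiculation_amplitude: float = 1.5  # mm
    core_intensity: float = 40.0  # HU
    background_intensity: float = -300.0  # HU; mixed lung/soft-tissue surround
    texture_correlation_length: float = 3.0  # mm
    noise_sd: float = 20.0  # HU, sd of the correlated texture field
    edge_blur_fwhm: float = 2.5  # mm; partial-volume ramp at the lesion boundary
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0 or self.edge_blur_fwhm < 0:
            raise ValueError("noise_sd and edge_blur_fwhm must be >= 0")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be > 0")
        if self.spiculation_count < 0 or self.spiculation_amplitude < 0:
            raise ValueError("spiculation parameters must be >= 0")
        if not np.isfinite([self.core_intensity, self.background_intensity]).all():
            raise ValueError("intensities must be finite")
        rmax = self.lesion_radius + self.spiculation_amplitude
        for size, sp in zip(self.grid_shape, self.spacing):
            half_extent = (size / 2.0 - 2.0) * sp  # keep a 2-voxel margin
            if rmax > half_extent:
                raise ValueError(
                    f"lesion (radius {self.lesion_radius} mm + spicules "
                    f"{self.spiculation_amplitude} mm) does not fit a "
                    f"{self.grid_shape} grid at spacing {self.spacing} with a "
                    f"2-voxel margin (axis half-extent {half_extent:.1f} mm)"
                )


@dataclass
class ObserverModel:
    """How one observer deviates from the true boundary.

    ``boundary_jitter_sd`` is the standard deviation (mm) of the smooth
    random radial displacement a manual observer applies;
    ``systematic_bias`` a signed constant dilation (+) / erosion (-) in mm;
    ``smoothing_fwhm`` the extra contour smoothing of manual outlines.
    Semi-automatic observers place ``n_seed_strokes`` foreground strokes.
    """

    kind: str = "manual"  # "manual" | "semiauto"
    boundary_jitter_sd: float = 1.5  # mm
    smoothing_fwhm: float = 3.0  # mm
    systematic_bias: float = 0.0  # mm
    n_seed_strokes: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("manual", "semiauto"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if self.boundary_jitter_sd < 0 or self.smoothing_fwhm < 0:
            raise ValueError("boundary_jitter_sd and smoothing_fwhm must be >= 0")
        if self.kind == "semiauto" and self.n_seed_strokes < 1:
            raise ValueError("semiauto observers need n_seed_strokes >= 1")


@dataclass
class PhantomRanges:
    """Uniform sampling ranges for per-tumor phantom parameters."""

    lesion_radius: tuple[float, float] = (6.0, 10.0)
    spiculation_count: tuple[int, int] = (4, 12)
    spiculation_amplitude: tuple[float, float] = (0.8, 2.0)
    core_intensity: tuple[float, float] = (0.0, 100.0)
    noise_sd: tuple[float, float] = (10.0, 30.0)
    texture_correlation_length: tuple[float, float] = (2.0, 4.5)


@dataclass
class StudyConfig:
    """Full study design: 20 tumors, 5 manual + 3x2 semi-automatic masks each."""

    n_tumors: int = 20
    n_manual_observers: int = 5
    n_semiauto_observers: int = 3
    n_semiauto_runs: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    ranges: PhantomRanges = field(default_factory=PhantomRanges)
    manual_model: ObserverModel = field(
        default_factory=lambda: ObserverModel(
            kind="manual", boundary_jitter_sd=0.6, smoothing_fwhm=3.0
        )
    )
    semiauto_model: ObserverModel = field(
        default_factory=lambda: ObserverModel(
            kind="semiauto", boundary_jitter_sd=0.0, smoothing_fwhm=0.0, n_seed_strokes=4
        )
    )
    manual_bias_sd: float = 0.3  # mm; per-observer systematic style
    semiauto_bias_sd: float = 0.15  # mm; applied to stroke margins
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if self.n_manual_observers < 2 or self.n_semiauto_observers < 2:
            raise ValueError("need >= 2 observers per group")
        if self.n_semiauto_runs < 1:
            raise ValueError("n_semiauto_runs must be >= 1")
        self.phantom.validate()

    @property
    def n_masks_per_tumor(self) -> int:
        return self.n_manual_observers + self.n_semiauto_observers * self.n_semiauto_runs


@dataclass
class SegRecord:
    """One observer segmentation of one tumor."""

    group: str  # "manual" | "semiauto"
    observer: int
    run: int
    mask: SegMask
    seed: int


@dataclass
class TumorCase:
    tumor_id: int
    volume: ImageVolume
    truth: SegMask
    segmentations: list[SegRecord]


@dataclass
class StudyDataset:
    config: StudyConfig
    tumors: list[TumorCase]


# ---------------------------------------------------------------------------
# phantom generation


def _physical_coords(shape, spacing):
    """Per-axis offsets (mm) of voxel centers from the grid center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * sp for n, sp in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _correlated_noise(rng, shape, spacing, corr_length, sd):
    """Gaussian-filtered white noise, rescaled to the requested sd."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_length / sp, 1e-6) for sp in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s * sd
    return smooth


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, SegMask]:
    """Generate one spiculated tumor phantom and its ground-truth mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = _physical_coords(spec.grid_shape, spec.spacing)
    r = np.sqrt(zz**2 + yy**2 + xx**2)

    radius_field = np.full(spec.grid_shape, spec.lesion_radius)
    if spec.spiculation_count > 0 and spec.spiculation_amplitude > 0:
        with np.errstate(invalid="ignore"):
            uz, uy, ux = zz / r, yy / r, xx / r
        dirs = rng.standard_normal((spec.spiculation_count, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for vz, vy, vx in dirs:
            cosang = np.clip(uz * vz + uy * vy + ux * vx, -1.0, 1.0)
            ang = np.arccos(cosang)
            bump = spec.spiculation_amplitude * np.exp(
                -((ang / _SPICULE_ANGULAR_WIDTH) ** 2)
            )
            radius_field += np.where(np.isfinite(bump), bump, 0.0)

    mask = r <= radius_field
    mask[tuple(s // 2 for s in spec.grid_shape)] = True  # center voxel (r=0)

    intensity = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    intensity[mask] = spec.core_intensity
    if spec.edge_blur_fwhm > 0:
        # partial-volume effect: the core/background step becomes a ramp
        sigma = [spec.edge_blur_fwhm / 2.3548 / sp for sp in spec.spacing]
        intensity = ndimage.gaussian_filter(intensity, sigma=sigma)
    if spec.noise_sd > 0:
        intensity += _correlated_noise(
            rng, spec.grid_shape, spec.spacing, spec.texture_correlation_length, spec.noise_sd
        )
    return ImageVolume(intensity, spec.spacing), SegMask(mask, spec.spacing)


# ---------------------------------------------------------------------------
# observer simulation


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, mm; negative inside."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def _largest_component(mask: np.ndarray) -> np.ndarray:
    comp, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
    return comp == (int(np.argmax(sizes)) + 1)


def smooth_mask(mask: np.ndarray, fwhm: float, spacing) -> np.ndarray:
    """Contour smoothing: Gaussian-blur the indicator, re-threshold at 0.5."""
    if fwhm <= 0:
        return mask.copy()
    sigma = [fwhm / 2.3548 / sp for sp in spacing]
    return ndimage.gaussian_filter(mask.astype(float), sigma=sigma) > 0.5


def simulate_manual_mask(
    truth: SegMask, model: ObserverModel, spacing: tuple[float, float, float] | None = None
) -> SegMask:
    """Simulate one manual delineation of ``truth``.

    The truth boundary is displaced by a smooth correlated random field
    (sd = ``boundary_jitter_sd`` mm) plus the observer's systematic bias,
    then the contour is smoothed. The result is the largest connected
    component; an error is raised if the perturbation empties the mask.
    """
    model.validate()
    if model.kind != "manual":
        raise ValueError("simulate_manual_mask requires a manual-kind ObserverModel")
    spacing = truth.spacing if spacing is None else spacing
    rng = np.random.default_rng(model.seed)
    sdf = _signed_distance(truth.data, spacing)
    if model.boundary_jitter_sd > 0:
        corr = max(model.smoothing_fwhm, min(spacing))
        disp = _correlated_noise(
            rng, truth.data.shape, spacing, corr, model.boundary_jitter_sd
        )
    else:
        disp = np.zeros_like(sdf)
    perturbed = sdf <= disp + model.systematic_bias
    out = smooth_mask(perturbed, model.smoothing_fwhm, spacing)
    out = _largest_component(out)
    if not out.any():
        raise ValueError("boundary perturbation emptied the mask")
    return SegMask(out, spacing)


# fixed "around the tumor" marking directions (axes + diagonals), jittered
# per observer when strokes are placed
_BG_DIRECTIONS = np.array(
    [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
        (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1),
    ],
    dtype=float,
)


def _random_stroke(rng, allowed: np.ndarray, length: int = 5) -> np.ndarray:
    """A short straight stroke of voxels inside ``allowed``."""
    coords = np.argwhere(allowed)
    start = coords[rng.integers(len(coords))]
    direction = rng.integers(-1, 2, size=3)
    if not direction.any():
        direction = np.array([0, 1, 0])
    stroke = [start]
    p = start.copy()
    for _ in range(length - 1):
        q = p + direction
        if (q < 0).any() or (q >= allowed.shape).any() or not allowed[tuple(q)]:
            break
        stroke.append(q.copy())
        p = q
    return np.array(stroke)


def simulate_semiauto_mask(
    volume: ImageVolume,
    truth: SegMask,
    model: ObserverModel,
    margin_voxels: int = 2,
    max_iters: int = 500,
) -> SegMask:
    """Simulate one semi-automatic (GrowCut) segmentation.

    Foreground strokes are placed at random well inside the lesion
    (inside the surface eroded by 20% of the effective radius), background
    strokes on a shell around it, and the GrowCut automaton is run followed
    by island removal. The observer's ``systematic_bias`` shifts the stroke
    margins, modeling a consistently tight or generous marking style.
    """
    model.validate()
    if model.kind != "semiauto":
        raise ValueError("simulate_semiauto_mask requires a semiauto-kind ObserverModel")
    truth.check_aligned(volume)
    spacing = truth.spacing
    rng = np.random.default_rng(model.seed)

    r_eff = (3.0 * truth.volume_mm3() / (4.0 * np.pi)) ** (1.0 / 3.0)
    margin_mm = 0.2 * r_eff
    sdf = _signed_distance(truth.data, spacing)

    interior = sdf <= -(margin_mm - model.systematic_bias)
    if not interior.any():
        interior = sdf <= sdf.min() + min(spacing)  # tiny lesion: deepest voxels
    seeds = np.zeros(truth.shape, dtype=np.int8)
    for _ in range(model.n_seed_strokes):
        for p in _random_stroke(rng, interior):
            seeds[tuple(p)] = 1

    # background marks on a shell around the lesion, one per direction,
    # with random angular jitter
    lo = margin_mm + model.systematic_bias
    hi = 3.0 * margin_mm + model.systematic_bias
    shell = (sdf >= lo) & (sdf <= hi)
    if not shell.any():
        raise ValueError("no room for background strokes around the lesion")
    shell_coords = np.argwhere(shell)
    center = np.array([(n - 1) / 2.0 for n in truth.shape])
    offsets = (shell_coords - center) * np.asarray(spacing)
    norms = np.linalg.norm(offsets, axis=1, keepdims=True)
    units = offsets / np.maximum(norms, 1e-9)
    for d in _BG_DIRECTIONS:
        d = d + 0.35 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        best = int(np.argmax(units @ d))
        seeds[tuple(shell_coords[best])] = 2

    result = growcut.segment(
        volume.data, seeds, margin_voxels=margin_voxels, max_iters=max_iters
    )
    if not result.converged:
        raise RuntimeError(
            f"GrowCut did not converge within {max_iters} iterations "
            f"(ROI size {int(result.roi.sum())} voxels)"
        )
    return growcut.postprocess(result.labels, foreground_class=1, spacing=spacing)


# ---------------------------------------------------------------------------
# full study generation


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(config: StudyConfig, out_dir=None) -> StudyDataset:
    """Generate the full synthetic study from ``config.master_seed``.

    Per tumor: a phantom volume + truth mask, ``n_manual_observers`` manual
    masks, and ``n_semiauto_observers`` x ``n_semiauto_runs`` semi-automatic
    masks. Per-observer systematic biases are drawn once and shared across
    tumors (an observer's style is consistent). If ``out_dir`` is given the
    dataset is persisted (volumes, masks, manifest) via the pipeline I/O
    layer.
    """
    config.validate()
    master = np.random.SeedSequence(config.master_seed)
    bias_rng = np.random.default_rng(_seed_from(master))
    manual_biases = bias_rng.normal(0.0, config.manual_bias_sd, config.n_manual_observers)
    semi_biases = bias_rng.normal(0.0, config.semiauto_bias_sd, config.n_semiauto_observers)

    tumor_seeds = master.spawn(config.n_tumors)
    tumors: list[TumorCase] = []
    for t, tss in enumerate(tumor_seeds):
        children = tss.spawn(1 + config.n_manual_observers
                             + config.n_semiauto_observers * config.n_semiauto_runs)
        param_rng = np.random.default_rng(_seed_from(children[0]))
        rg = config.ranges
        spec = replace(
            config.phantom,
            lesion_radius=param_rng.uniform(*rg.lesion_radius),
            spiculation_count=int(param_rng.integers(rg.spiculation_count[0],
                                                     rg.spiculation_count[1] + 1)),
            spiculation_amplitude=param_rng.uniform(*rg.spiculation_amplitude),
            core_intensity=param_rng.uniform(*rg.core_intensity),
            noise_sd=param_rng.uniform(*rg.noise_sd),
            texture_correlation_length=param_rng.uniform(*rg.texture_correlation_length),
            seed=_seed_from(children[0]),
        )
        volume, truth = generate_phantom(spec)

        segs: list[SegRecord] = []
        ci = 1
        for obs in range(config.n_manual_observers):
            seed = _seed_from(children[ci]); ci += 1
            m = replace(config.manual_model, systematic_bias=float(manual_biases[obs]),
                        seed=seed)
            segs.append(SegRecord("manual", obs, 0, simulate_manual_mask(truth, m), seed))
        for obs in range(config.n_semiauto_observers):
            for run in range(config.n_semiauto_runs):
                seed = _seed_from(children[ci]); ci += 1
                m = replace(config.semiauto_model,
                            systematic_bias=float(semi_biases[obs]), seed=seed)
                segs.append(
                    SegRecord("semiauto", obs, run,
                              simulate_semiauto_mask(volume, truth, m), seed)
                )
        tumors.append(TumorCase(t, volume, truth, segs))

    dataset = StudyDataset(config, tumors)
    if out_dir is not None:
        from .pipeline import write_dataset

        write_dataset(dataset, out_dir)
    return dataset
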