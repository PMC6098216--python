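"""Seeded synthetic multi-tissue phantoms rendered under two scanner models.

The generator produces small 3D "head" anatomies — a brain ellipsoid with a
CSF shell, gray-matter ring and white-matter core, plus two lateralized
ellipsoidal target structures — and renders each anatomy under a
parameterized scanner model: per-tissue mean intensities, a monotone global
gamma remap, a smooth multiplicative bias field, Gaussian point-spread
blur, and additive noise, applied in that order.  Rendering the same
anatomy under two scanner models yields same-subject rescan pairs, the
unlabeled data the feature-space transformation is learned from.

Two scanner-gap presets ship with the package: a mild one (slightly
different gamma and bias; same tissue contrast ordering) and a severe one
(inverted tissue contrast, stronger gamma, bias and noise), emulating the
small and large cross-protocol appearance differences seen in multi-site
T1 data versus different pulse sequences.  The global remap is monotone,
so tissue classes map one-to-one between scanners — the regime the FST is
designed for.

Every quantity is a pure function of (config, master_seed): all randomness
flows through named sub-seeds spawned from the master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import BrainMask, ImageVolume

__all__ = [
    "ScannerModel",
    "StudyConfig",
    "Anatomy",
    "PairRecord",
    "PhantomStudy",
    "scanner_preset",
    "generate_anatomy",
    "render_scan",
    "generate_study",
]

# Tissue codes in the rendered label volume.
BACKGROUND, CSF, GRAY, WHITE, STRUCTURE = 0, 1, 2, 3, 4

# Structure codes in the evaluation label volume.
LEFT, RIGHT = 1, 2


@dataclass(frozen=True)
class ScannerModel:
    """Appearance model of one scanner / scan protocol.

    tissue_means are on a nominal [0, 1] scale indexed by tissue code
    (background, CSF, gray, white, target structure).  The gamma exponent
    is a strictly monotone global intensity remap; the bias field is a
    smooth multiplicative inhomogeneity of the given relative amplitude and
    correlation length; psf_sigma_mm is the Gaussian point-spread width and
    noise_sd the additive noise level.
    """

    name: str
    tissue_means: tuple[float, float, float, float, float]
    gamma: float = 1.0
    bias_amplitude: float = 0.0
    bias_smoothness_mm: float = 12.0
    psf_sigma_mm: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0 for a monotone remap")
        if self.noise_sd < 0 or self.psf_sigma_mm < 0 or self.bias_amplitude < 0:
            raise ValueError("noise, PSF and bias amplitudes must be >= 0")

    def param_key(self) -> int:
        """Stable integer digest of the acquisition parameters.

        Render noise seeds are derived from this key, so two scanner models
        with identical parameters produce identical acquisitions of the
        same anatomy — the 'same scanner' limit is then exact.
        """
        payload = repr(
            (self.tissue_means, self.gamma, self.bias_amplitude,
             self.bias_smoothness_mm, self.psf_sigma_mm, self.noise_sd)
        ).encode()
        return zlib.crc32(payload)


def scanner_preset(name: str) -> ScannerModel:
    """Named scanner models: 'reference', 'harp_like', 'rss_like'.

    'reference' is the source scanner.  'harp_like' differs mildly (same
    contrast ordering, slight gamma and bias differences); 'rss_like'
    differs severely (inverted tissue contrast, gamma 1.6, stronger bias
    and noise).
    """
    presets = {
        "reference": ScannerModel(
            "reference",
            tissue_means=(0.02, 0.20, 0.50, 0.80, 0.62),
            gamma=1.0,
            bias_amplitude=0.05,
            psf_sigma_mm=1.0,
            noise_sd=0.03,
        ),
        "harp_like": ScannerModel(
            "harp_like",
            tissue_means=(0.02, 0.25, 0.55, 0.85, 0.68),
            gamma=1.1,
            bias_amplitude=0.10,
            psf_sigma_mm=1.2,
            noise_sd=0.03,
        ),
        "rss_like": ScannerModel(
            "rss_like",
            tissue_means=(0.02, 0.85, 0.50, 0.22, 0.38),
            gamma=1.6,
            bias_amplitude=0.20,
            psf_sigma_mm=1.5,
            noise_sd=0.05,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown scanner preset '{name}'; choose from {sorted(presets)}")
    return presets[name]


@dataclass
class Anatomy:
    """One subject's ground truth: tissue volume, structure labels, mask."""

    tissues: np.ndarray  # tissue codes 0..4
    labels: np.ndarray  # 0 background, 1 left structure, 2 right structure
    mask: BrainMask
    spacing: tuple[float, float, float]


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def smooth_deformation(shape, amplitude_vox: float, smoothness_vox: float, rng) -> np.ndarray:
    """Smooth random displacement field, (3, *shape), max norm ~= amplitude."""
    field_ = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), smoothness_vox) for _ in range(3)]
    )
    norm = np.sqrt((field_**2).sum(axis=0)).max()
    if norm > 0:
        field_ *= amplitude_vox / norm
    return field_


def warp_labels(labels: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Warp an integer label volume by a displacement field (nearest neighbor)."""
    coords = np.indices(labels.shape, dtype=np.float64) + displacement
    return ndimage.map_coordinates(labels, coords, order=0, mode="nearest")


def generate_anatomy(
    seed: int,
    grid_shape=(48, 48, 48),
    spacing=(1.0, 1.0, 1.0),
    deform_amplitude_vox: float = 0.8,
) -> Anatomy:
    """A seeded multi-tissue head with two lateralized target structures.

    Ellipsoid positions and sizes are jittered per subject and the whole
    label volume receives a small smooth random deformation, so no two
    subjects (or seeds) share an anatomy.  Raises if the grid is too small
    to hold the structures.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if min(grid_shape) < 32:
        raise ValueError(f"grid {grid_shape} too small; need at least 32 per axis")
    rng = np.random.default_rng(seed)
    shape = np.array(grid_shape, dtype=float)
    center = shape / 2 + rng.uniform(-1.0, 1.0, size=3)

    brain_ax = shape * 0.42 * rng.uniform(0.95, 1.05, size=3)
    tissues = np.zeros(grid_shape, dtype=np.int16)
    brain = _ellipsoid(grid_shape, center, brain_ax)
    tissues[brain] = CSF
    tissues[_ellipsoid(grid_shape, center, brain_ax * 0.88)] = GRAY
    tissues[_ellipsoid(grid_shape, center, brain_ax * 0.58)] = WHITE

    labels = np.zeros(grid_shape, dtype=np.int16)
    base_ax = np.array([0.105, 0.145, 0.105]) * shape
    for side, sign in ((LEFT, -1.0), (RIGHT, 1.0)):
        c = center + np.array([sign * 0.46 * brain_ax[0], 0.0, 0.0])
        c += rng.uniform(-1.5, 1.5, size=3)
        ax = base_ax * rng.uniform(0.9, 1.1, size=3)
        ell = _ellipsoid(grid_shape, c, ax)
        if not ell.any():
            raise ValueError("target structure fell outside the grid")
        labels[ell] = side

    if deform_amplitude_vox > 0:
        disp = smooth_deformation(grid_shape, deform_amplitude_vox, 4.0, rng)
        tissues = warp_labels(tissues, disp)
        labels = warp_labels(labels, disp)

    left, right = labels == LEFT, labels == RIGHT
    if not left.any() or not right.any():
        raise ValueError("a target structure is empty after deformation")
    if (left & right).any():
        raise ValueError("target structures overlap")
    labels[~brain] = 0  # keep structures inside the head
    tissues[labels > 0] = STRUCTURE
    tissues[~brain & (tissues > 0)] = 0
    return Anatomy(tissues, labels, BrainMask(tissues > 0), tuple(spacing))


def render_scan(anatomy: Anatomy, scanner: ScannerModel, seed: int) -> ImageVolume:
    """Render one acquisition: means -> gamma -> bias -> PSF -> noise."""
    rng = np.random.default_rng(seed)
    spacing = anatomy.spacing
    means = np.asarray(scanner.tissue_means, dtype=np.float64)
    img = means[anatomy.tissues]
    img = np.clip(img, 0.0, None) ** scanner.gamma
    if scanner.bias_amplitude > 0:
        sig = tuple(scanner.bias_smoothness_mm / s for s in spacing)
        raw = ndimage.gaussian_filter(rng.standard_normal(anatomy.tissues.shape), sig)
        peak = np.abs(raw).max()
        if peak > 0:
            raw /= peak
        img = img * (1.0 + scanner.bias_amplitude * raw)
    if scanner.psf_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, tuple(scanner.psf_sigma_mm / s for s in spacing))
    if scanner.noise_sd > 0:
        img = img + rng.normal(0.0, scanner.noise_sd, size=img.shape)
    return ImageVolume(img, spacing)


@dataclass(frozen=True)
class StudyConfig:
    """Sizes and scanner models of a phantom study.

    Defaults model the severe cross-protocol regime at desk scale: 3
    labeled training subjects on scanner A, 3 labeled test subjects on
    scanner B, 2 unlabeled rescan-pair subjects scanned on both.
    """

    n_train: int = 3
    n_test: int = 3
    n_pairs: int = 2
    n_atlas_extra: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    scanner_a: ScannerModel = field(default_factory=lambda: scanner_preset("reference"))
    scanner_b: ScannerModel = field(default_factory=lambda: scanner_preset("rss_like"))
    anatomy_deform_vox: float = 0.8
    atlas_deform_vox: float = 1.5  # stands in for residual registration error

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_test, self.n_pairs) < 1:
            raise ValueError("n_train, n_test and n_pairs must all be >= 1")
        if self.n_atlas_extra < 0:
            raise ValueError("n_atlas_extra must be >= 0")


@dataclass
class SubjectRecord:
    subject_id: str
    anatomy: Anatomy
    images: dict[str, ImageVolume]  # keyed by scanner slot "A"/"B"


@dataclass
class PairRecord:
    """Same-anatomy rescan pair: one subject under both scanner models."""

    subject_id: str
    anatomy: Anatomy
    image_a: ImageVolume
    image_b: ImageVolume


@dataclass
class PhantomStudy:
    """A complete synthetic study: labeled train/test subjects, unlabeled
    rescan pairs, and simulated registered atlases per target image."""

    config: StudyConfig
    master_seed: int
    train: list[SubjectRecord]
    test: list[SubjectRecord]
    pairs: list[PairRecord]
    extra_atlas_labels: list[np.ndarray] = field(default_factory=list)
    #: atlases[target_subject_id] = list of structure-label volumes
    #: (0/1/2) standing in for training atlases registered onto that image.
    atlases: dict[str, list[np.ndarray]] = field(default_factory=dict)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.config.spacing


_ROLE_TAGS = {"train": 1, "test": 2, "pair": 3, "extra": 4, "atlas": 5}


def _sub_seed(master_seed: int, role: str, *extra: int) -> np.random.SeedSequence:
    """Named sub-seed derivation; documented so stages are reproducible."""
    return np.random.SeedSequence([int(master_seed), _ROLE_TAGS[role], *map(int, extra)])


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(config: StudyConfig, master_seed: int) -> PhantomStudy:
    """Generate a full study as a pure function of (config, master_seed).

    Train, test and pair subjects use disjoint anatomy seeds.  Every
    subject is rendered under both scanner models; the pipeline only sees
    scanner A for training subjects and scanner B for test subjects, but
    having both renders makes same-scanner reference experiments possible.
    Registered atlases for each target image are simulated by applying a
    small smooth deformation to the training structure labels (standing in
    for non-rigid registration output, which is outside this package).
    """
    cfg = config

    def make_subject(role: str, idx: int) -> SubjectRecord:
        ana = generate_anatomy(
            _seed_int(_sub_seed(master_seed, role, idx, 0)),
            cfg.grid_shape,
            cfg.spacing,
            cfg.anatomy_deform_vox,
        )
        images = {}
        for slot, scanner in (("A", cfg.scanner_a), ("B", cfg.scanner_b)):
            seed = _seed_int(_sub_seed(master_seed, role, idx, scanner.param_key()))
            images[slot] = render_scan(ana, scanner, seed)
        return SubjectRecord(f"{role}{idx}", ana, images)

    train = [make_subject("train", i) for i in range(cfg.n_train)]
    test = [make_subject("test", i) for i in range(cfg.n_test)]
    pairs = []
    for i in range(cfg.n_pairs):
        sub = make_subject("pair", i)
        pairs.append(PairRecord(sub.subject_id, sub.anatomy, sub.images["A"], sub.images["B"]))

    extra = [
        generate_anatomy(
            _seed_int(_sub_seed(master_seed, "extra", i, 0)),
            cfg.grid_shape,
            cfg.spacing,
            cfg.anatomy_deform_vox,
        ).labels
        for i in range(cfg.n_atlas_extra)
    ]

    atlases: dict[str, list[np.ndarray]] = {}
    atlas_sources = [t.anatomy.labels for t in train] + extra
    targets = [(s.subject_id) for s in train + test] + [p.subject_id for p in pairs]
    for t_idx, target_id in enumerate(targets):
        regs = []
        for a_idx, src_labels in enumerate(atlas_sources):
            rng = np.random.default_rng(
                _seed_int(_sub_seed(master_seed, "atlas", t_idx, a_idx))
            )
            disp = smooth_deformation(cfg.grid_shape, cfg.atlas_deform_vox, 4.0, rng)
            regs.append(warp_labels(src_labels, disp))
        atlases[target_id] = regs
    return PhantomStudy(cfg, master_seed, train, test, pairs, extra, atlases)
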