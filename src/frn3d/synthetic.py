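"""Synthetic two-class cohorts of brain-like 3D volumes.

Real gray-matter density maps from a patient/control study are not publicly
shareable, so this module generates stand-in cohorts with a known statistical
structure: a smooth baseline texture (Gaussian-filtered white noise) inside an
ellipsoidal "brain" mask, an additive class effect confined to a few spherical
regions (emulating localized group-level gray-matter density differences), and
independent voxel noise.  Every quantity of interest — effect size in units of
the noise SD, region geometry, smoothness, cohort size — is explicit in
:class:`SyntheticConfig`, and the whole cohort is a pure function of one seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticConfig",
    "VolumeSample",
    "SyntheticCohort",
    "make_brain_mask",
    "sample_volume",
    "generate_cohort",
    "export_cohort",
]

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model for one cohort.

    ``effect_size`` is the class-mean intensity offset inside the effect
    regions, expressed in units of ``noise_sd``; 0 gives an exact null in
    which both classes share one distribution.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_per_class: int = 34
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_effect_regions: int = 4
    region_radius_vox: int = 4
    smoothness_fwhm_vox: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError("shape must be a triple with every entry >= 8")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_effect_regions < 0:
            raise ValueError("n_effect_regions must be >= 0")
        if self.region_radius_vox < 1:
            raise ValueError("region_radius_vox must be a positive integer")
        if self.smoothness_fwhm_vox <= 0:
            raise ValueError("smoothness_fwhm_vox must be positive")


@dataclass
class VolumeSample:
    volume: np.ndarray
    label: int  # 0 = control, 1 = patient
    subject_id: str


@dataclass
class SyntheticCohort:
    samples: list[VolumeSample]
    config: SyntheticConfig
    effect_region_centers: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return make_brain_mask(self.config.shape, self.config.seed)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])


def make_brain_mask(shape: tuple[int, int, int], seed: int) -> np.ndarray:
    """Axis-aligned ellipsoid occupying 30-70% of each axis, centred in the box.

    Deterministic in ``seed``; the fraction per axis is drawn uniformly.
    """
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("shape must be a triple with every entry >= 8")
    rng = np.random.default_rng(seed)
    fracs = rng.uniform(0.3, 0.7, size=3)
    center = (np.asarray(shape) - 1) / 2.0
    semi = fracs * np.asarray(shape) / 2.0
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask = dist2 <= 1.0
    assert mask.any()
    return mask


def _effect_field(shape, centers, radius) -> np.ndarray:
    """Indicator of the union of spheres of ``radius`` voxels around centers."""
    out = np.zeros(shape, dtype=bool)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    for c in centers:
        dist2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        out |= dist2 <= radius**2
    return out


def sample_volume(config: SyntheticConfig, label: int, centers,
                  rng: np.random.Generator, *, mask: np.ndarray | None = None,
                  subject_id: str = "sub-000") -> VolumeSample:
    """Draw one volume: smooth baseline + localized class effect + noise.

    The baseline field is white noise filtered at ``smoothness_fwhm_vox`` and
    rescaled to unit SD; the class effect adds ``effect_size * noise_sd``
    inside the spheres for label-1 subjects; independent Gaussian noise of SD
    ``noise_sd`` is added everywhere; the brain mask zeroes the outside.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if mask is None:
        mask = make_brain_mask(config.shape, config.seed)
    for c in centers:
        if not mask[tuple(int(v) for v in c)]:
            raise ValueError(f"effect region center {tuple(c)} lies outside the brain mask")
    sigma = config.smoothness_fwhm_vox / FWHM_TO_SD
    base = gaussian_filter(rng.standard_normal(config.shape), sigma, mode="nearest")
    sd = base.std()
    if sd > 0:
        base /= sd
    vol = base + rng.normal(0.0, config.noise_sd, config.shape)
    if label == 1 and centers:
        vol += config.effect_size * config.noise_sd * _effect_field(
            config.shape, centers, config.region_radius_vox
        )
    vol *= mask
    return VolumeSample(volume=vol, label=label, subject_id=subject_id)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Balanced two-class cohort; all randomness flows from ``config.seed``.

    Effect-region centers are drawn once, uniformly from the mask interior,
    and shared by every sample, so the class signal is spatially consistent
    across subjects.
    """
    mask = make_brain_mask(config.shape, config.seed)
    rng = np.random.default_rng(config.seed)
    interior = np.argwhere(mask)
    idx = rng.choice(len(interior), size=config.n_effect_regions, replace=False)
    centers = [tuple(int(v) for v in interior[i]) for i in idx]

    samples = []
    for i in range(config.n_per_class):
        for label, tag in ((0, "hc"), (1, "pat")):
            sid = f"sub-{tag}-{i:03d}"
            samples.append(sample_volume(config, label, centers, rng,
                                         mask=mask, subject_id=sid))
    return SyntheticCohort(samples=samples, config=config,
                           effect_region_centers=centers)


def export_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write every sample as NIfTI-1 (.nii.gz, 1 mm isotropic) plus a TSV
    manifest (subject_id, label, path); returns the manifest path."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "label", "path"])
        for s in cohort.samples:
            path = out_dir / f"{s.subject_id}.nii.gz"
            nib.save(nib.Nifti1Image(s.volume.astype(np.float32), np.eye(4)), path)
            writer.writerow([s.subject_id, s.label, path.name])
    return manifest


def load_cohort_manifest(manifest: str | Path) -> list[tuple[str, int, Path]]:
    """Read a manifest TSV; paths are resolved relative to the manifest."""
    manifest = Path(manifest)
    rows = []
    with open(manifest) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append((row["subject_id"], int(row["label"]),
                         manifest.parent / row["path"]))
    if not rows:
        raise ValueError(f"empty manifest: {manifest}")
    return rows
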