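"""Seeded multi-contrast phantoms with nested ellipsoidal tumor compartments.

Each phantom imitates the structure of a four-contrast brain MRI study
(T1, post-contrast T1, T2, FLAIR): a background, an edema envelope
(label 2), an enhancing rim inside it (label 4) and a necrotic core at the
center (label 1), each an axis-aligned ellipsoid, strictly nested
core ⊂ rim ⊂ edema.  Per-compartment mean intensities differ per contrast by
more than twice the noise standard deviation in at least one channel, so
every compartment is separable in principle.  Analytic ellipsoid volumes
give closed-form oracles for voxel counts; realism (bias fields, texture,
irregular morphology) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nifti import write_nifti

#: rows: background, core (label 1), edema (label 2), rim (label 4);
#: columns: T1-like, T1-Gd-like, T2-like, FLAIR-like mean intensities.
DEFAULT_INTENSITY = np.array(
    [
        [0.30, 0.30, 0.25, 0.25],  # background
        [0.20, 0.20, 0.60, 0.45],  # necrotic core: dark T1, bright T2
        [0.35, 0.30, 0.55, 0.70],  # edema: bright FLAIR
        [0.40, 0.80, 0.50, 0.55],  # enhancing rim: bright post-contrast T1
    ],
    dtype=np.float32,
)

_COMPARTMENT_LABELS = (0, 1, 2, 4)  # row order of the intensity table


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    n_contrasts: int = 4
    center: tuple[float, float, float] | None = None
    core_radii: tuple[float, float, float] = (4.0, 5.0, 6.0)
    rim_radii: tuple[float, float, float] = (7.0, 8.0, 9.0)
    edema_radii: tuple[float, float, float] = (10.0, 12.0, 14.0)
    intensity: np.ndarray = field(default_factory=lambda: DEFAULT_INTENSITY.copy())
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for a, b in zip(self.core_radii, self.rim_radii):
            if not a < b:
                raise SpecError(f"core radii {self.core_radii} must be strictly "
                                f"inside rim radii {self.rim_radii}")
        for a, b in zip(self.rim_radii, self.edema_radii):
            if not a < b:
                raise SpecError(f"rim radii {self.rim_radii} must be strictly "
                                f"inside edema radii {self.edema_radii}")
        intensity = np.asarray(self.intensity, dtype=np.float32)
        if intensity.shape != (4, self.n_contrasts):
            raise SpecError(
                f"intensity table must be [4 compartments x {self.n_contrasts} contrasts]"
            )
        if self.noise_sd > 0:
            sep = np.abs(intensity[1:] - intensity[0]).max(axis=1)
            if (sep <= 2 * self.noise_sd).any():
                raise SpecError(
                    "each compartment must differ from background by > 2*noise_sd "
                    "in at least one contrast"
                )

    @property
    def effective_center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple((s - 1) / 2.0 for s in self.shape)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (volume [H, W, D, n_contrasts] float32, labels [H, W, D] uint8)."""
    rng = np.random.default_rng(spec.seed)
    center = spec.effective_center
    edema = _ellipsoid_mask(spec.shape, center, spec.edema_radii)
    rim = _ellipsoid_mask(spec.shape, center, spec.rim_radii)
    core = _ellipsoid_mask(spec.shape, center, spec.core_radii)

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[edema] = 2          # edema shell
    labels[rim] = 4            # enhancing rim
    labels[core] = 1           # necrotic core

    intensity = np.asarray(spec.intensity, dtype=np.float32)
    volume = np.empty(spec.shape + (spec.n_contrasts,), dtype=np.float32)
    for row, lab in enumerate(_COMPARTMENT_LABELS):
        volume[labels == lab] = intensity[row]
    if spec.noise_sd > 0:
        volume += rng.normal(0.0, spec.noise_sd, size=volume.shape).astype(np.float32)
    return volume, labels


def analytic_ellipsoid_volume(radii: tuple[float, float, float]) -> float:
    a, b, c = radii
    return 4.0 / 3.0 * np.pi * a * b * c


def _jitter(rng: np.random.Generator, values, rel: float = 0.15):
    return tuple(float(v * (1.0 + rng.uniform(-rel, rel))) for v in values)


def training_template(shape: tuple[int, int, int] = (32, 32, 32)) -> PhantomSpec:
    """Template whose compartments stay resolvable at the given resolution.

    Radii scale with the volume side so the enhancing rim and the edema
    envelope are each several voxels thick — thinner shells than roughly two
    voxels carry their boundary below the 4-voxel patch granularity and are
    not learnable at desk scale.
    """
    s = np.array(shape) / 32.0
    return PhantomSpec(
        shape=tuple(shape),
        core_radii=tuple(np.array((2.5, 3.0, 3.5)) * s),
        rim_radii=tuple(np.array((4.5, 5.0, 5.5)) * s),
        edema_radii=tuple(np.array((7.5, 8.5, 9.5)) * s),
    )


def jittered_spec(template: PhantomSpec, case_seed: int) -> PhantomSpec:
    """Per-case variation: center shifted by up to 8% of the side, radii
    scaled by up to ±15% per axis; margins in the default templates keep the
    strict compartment nesting intact."""
    jr = np.random.default_rng(case_seed)
    center = tuple(
        float(c + jr.uniform(-0.08, 0.08) * s)
        for c, s in zip(template.effective_center, template.shape)
    )
    return PhantomSpec(
        shape=template.shape,
        n_contrasts=template.n_contrasts,
        center=center,
        core_radii=_jitter(jr, template.core_radii),
        rim_radii=_jitter(jr, template.rim_radii),
        edema_radii=_jitter(jr, template.edema_radii),
        intensity=template.intensity,
        noise_sd=template.noise_sd,
        seed=case_seed,
    )


def generate_cases(n: int, template: PhantomSpec,
                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """``n`` in-memory (volume, labels) pairs, jittered around the template."""
    rng = np.random.default_rng(seed)
    return [
        generate_phantom(jittered_spec(template, int(rng.integers(0, 2**31))))
        for _ in range(n)
    ]


def generate_dataset(n: int, template: PhantomSpec, out_dir: str | Path,
                     seed: int = 0) -> pd.DataFrame:
    """Write ``n`` phantoms (image + label NIfTI pairs) and a manifest CSV.

    Centers and radii are jittered around the template, deterministically
    from ``seed``; each case additionally gets its own noise seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    affine = np.eye(4, dtype=np.float64)
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31))
        spec = jittered_spec(template, case_seed)
        volume, labels = generate_phantom(spec)
        case_id = f"phantom_{i:04d}"
        img_path = out_dir / f"{case_id}_image.nii.gz"
        lab_path = out_dir / f"{case_id}_label.nii.gz"
        write_nifti(volume, affine, img_path, dtype=np.float32)
        write_nifti(labels, affine, lab_path, dtype=np.uint8)
        rows.append({"case_id": case_id, "seed": case_seed,
                     "image": str(img_path), "label": str(lab_path)})
    manifest = pd.DataFrame(rows, columns=["case_id", "seed", "image", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
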