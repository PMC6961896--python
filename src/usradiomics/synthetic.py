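"""Synthetic ultrasound-like cohorts for pipeline testing.

Real B-mode speckle is granular multiplicative interference noise whose
correlation length depends on the imaging system and the tissue.  The
generator mimics this first-order structure: a smooth base intensity
field is multiplied by unit-mean Gamma speckle that has been blurred
with a Gaussian kernel, and the class signal enters through the blur
width (the speckle correlation length), which co-occurrence and
run-length features are sensitive to.  Tumors are random ellipses;
labels are Bernoulli draws at the study prevalences (0.21 training,
0.27 validation); clinical covariates are drawn from the cohort
distributions but, by default, carry no signal — the signature is
image-only.

This is not a physical ultrasound simulation: there is no point-spread
RF model, attenuation, or shadowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .imaging import GrayImage, RoiMask

__all__ = ["SyntheticConfig", "SyntheticPatient", "generate_image", "generate_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``smooth_neg`` is the pre-speckle Gaussian blur width (pixels) of
    the LN-negative class; the LN-positive class uses
    ``smooth_neg + delta``.  ``delta = 0`` is the null configuration:
    both classes share one image law.  ``gamma_shape`` controls the
    multiplicative-noise roughness (smaller = spikier speckle).
    """

    n_patients: int = 400
    prevalence: float = 0.21
    image_size: tuple[int, int] = (128, 128)
    axis_range: tuple[float, float] = (10.0, 28.0)  # ellipse semi-axes, px
    smooth_neg: float = 1.0
    delta: float = 2.0
    gamma_shape: float = 4.0
    base_intensity: float = 120.0
    base_amplitude: float = 25.0
    base_scale: float = 16.0  # blur width of the base field, px
    couple_central_lnm: bool = False
    seed: int = 0
    tag: str = "training"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.axis_range[0] < 4.0:
            raise ValueError("ellipse semi-axes must be >= 4 pixels")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    image: GrayImage
    mask: RoiMask
    label: int
    covariates: dict[str, float | str]


def _ellipse_mask(shape: tuple[int, int], rng: np.random.Generator,
                  axis_range: tuple[float, float]) -> np.ndarray:
    h, w = shape
    a = rng.uniform(*axis_range)
    b = rng.uniform(*axis_range)
    phi = rng.uniform(0.0, np.pi)
    radius = max(a, b) + 2.0
    if 2 * radius + 4 >= min(h, w):
        raise ValueError("ellipse cannot fit inside the image")
    cy = rng.uniform(radius + 2, h - radius - 2)
    cx = rng.uniform(radius + 2, w - radius - 2)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_image(config: SyntheticConfig, label: int,
                   rng: np.random.Generator, patient_id: str = "P0000") -> SyntheticPatient:
    """Draw one speckle image, its elliptical tumor mask and covariates.

    image = clip_0..255(round(M * S)) where M is a smooth base intensity
    field and S a Gaussian-blurred unit-mean Gamma speckle field whose
    blur width depends on the class label.
    """
    h, w = config.image_size
    s = config.smooth_neg + (config.delta if label else 0.0)
    base = gaussian_filter(rng.standard_normal((h, w)), config.base_scale)
    sd = base.std()
    if sd > 0:
        base = base / sd
    M = config.base_intensity + config.base_amplitude * base
    k = config.gamma_shape
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=(h, w))
    if s > 0:
        speckle = gaussian_filter(speckle, s)
    img = np.clip(np.rint(M * speckle), 0, 255)
    mask = _ellipse_mask((h, w), rng, config.axis_range)

    age = float(np.clip(rng.normal(45.0, 13.0), 17.0, 80.0))
    sex = "F" if rng.random() < 0.85 else "M"
    tumor = float(np.exp(rng.normal(np.log(17.0), 0.35)))
    if config.couple_central_lnm:
        p_central = 0.90 if label else 0.49
    else:
        p_central = 0.575
    central = int(rng.random() < p_central)
    return SyntheticPatient(
        patient_id=patient_id,
        image=GrayImage(img),
        mask=RoiMask(mask),
        label=int(label),
        covariates={"age": round(age, 1), "sex": sex,
                    "tumor_size_mm": round(tumor, 1), "central_lnm": central},
    )


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate a full cohort and its manifest.

    Labels are i.i.d. Bernoulli(prevalence); the manifest has one row
    per patient with label, cohort tag and covariates.  When ``out_dir``
    is given, images and masks are written as PNG and the manifest (plus
    the generator config) saved alongside, in the layout `imaging_io`
    manifests use.
    """
    if config.n_patients < 20:
        raise ValueError("cohort needs at least 20 patients")
    if config.n_patients * config.prevalence < 2:
        raise ValueError("too few expected positives for stratified CV")
    rng = np.random.default_rng(config.seed)
    labels = (rng.random(config.n_patients) < config.prevalence).astype(int)
    # guard the degenerate draw: stratified CV needs both classes
    if labels.sum() < 2:
        labels[:2] = 1
    if labels.sum() > config.n_patients - 2:
        labels[:2] = 0

    patients: list[SyntheticPatient] = []
    rows = []
    prefix = "T" if config.tag == "training" else "V"
    for i, lab in enumerate(labels):
        pid = f"{prefix}{i + 1:04d}"
        pat = generate_image(config, int(lab), rng, patient_id=pid)
        patients.append(pat)
        rows.append({
            "patient_id": pid,
            "image": f"images/{pid}.png",
            "mask": f"masks/{pid}.png",
            "label": int(lab),
            "cohort": config.tag,
            **pat.covariates,
        })
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for pat, row in zip(patients, rows):
            Image.fromarray(pat.image.pixels.astype(np.uint8)).save(out / row["image"])
            Image.fromarray((pat.mask.pixels * 255).astype(np.uint8)).save(out / row["mask"])
        manifest.to_csv(out / "manifest.csv", index=False)
        import dataclasses, json

        cfg = dataclasses.asdict(config)
        (out / "config.json").write_text(json.dumps(cfg, indent=2))
    return patients, manifest
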