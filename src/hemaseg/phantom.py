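"""Paired-phase CT phantom generator.

Real liver-hemangioma CT with paired non-contrast and venous acquisitions
is not publicly distributable, so the pipeline is exercised on a synthetic
phantom that carries the statistical structure the method assumes: two
geometrically identical HU-valued phases in which lesions are strongly
hypodense relative to parenchyma in the venous phase and only mildly
hypodense without contrast; lesion maximum diameters drawn from a
truncated normal (defaults mean 24.6 mm, sd 18.3 mm, range 3.2-87.5 mm);
0.75 x 0.75 mm in-plane spacing and 1.5 mm slice thickness; and the three
size strata Tiny (< 10 mm), Small ([10, 20) mm), Big (>= 20 mm).

Lesions are axis-aligned ellipses (ellipsoids in the thin 3-D stack mode)
on a textured uniform parenchyma background; anatomy (texture + lesions)
is shared between phases, while additive acquisition noise is drawn
independently per phase. The recorded lesion diameter is the one measured
on the rasterized mask (maximum pairwise boundary distance), mirroring how
lesion size is read off a scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigurationError, PlacementError
from .evaluation import max_diameter_mm, stratum_of

_MAX_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class DiameterDist:
    """Truncated-normal lesion diameter distribution (mm)."""

    mean_mm: float = 24.6
    sd_mm: float = 18.3
    min_mm: float = 3.2
    max_mm: float = 87.5

    def __post_init__(self):
        if not (self.min_mm < self.max_mm):
            raise ConfigurationError(f"diameter bounds invalid: [{self.min_mm}, {self.max_mm}]")
        if self.sd_mm <= 0:
            raise ConfigurationError("diameter sd must be positive")


@dataclass
class CTVolume:
    """HU-valued voxel grid with mm spacing and a phase tag."""

    data: np.ndarray
    spacing: tuple
    phase: str  # "noncontrast" | "venous"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if len(self.spacing) != self.data.ndim:
            raise ConfigurationError("spacing length must match dimensionality")


@dataclass(frozen=True)
class TumorRecord:
    center_mm: tuple
    diameter_mm: float      # measured on the rasterized mask
    stratum: str
    nominal_diameter_mm: float  # the sampled target diameter


@dataclass
class PhantomCase:
    noncontrast: CTVolume
    venous: CTVolume
    mask: np.ndarray
    tumor_records: list
    case_id: str = ""


@dataclass
class PhantomConfig:
    image_size: int = 512
    pixel_spacing_mm: tuple = (0.75, 0.75)
    slice_thickness_mm: float = 1.5
    n_tumors_per_slice: int = 1
    diameter_dist: DiameterDist = field(default_factory=DiameterDist)
    liver_hu: float = 60.0
    liver_texture_sd_hu: float = 5.0
    tumor_contrast_hu: dict = field(
        default_factory=lambda: {"noncontrast": -12.0, "venous": -40.0})
    noise_sd_hu: float = 8.0
    eccentricity_range: tuple = (1.0, 1.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors_per_slice < 0:
            raise ConfigurationError("n_tumors_per_slice must be >= 0")
        if self.noise_sd_hu < 0 or self.liver_texture_sd_hu < 0:
            raise ConfigurationError("noise scales must be >= 0")
        cnc = abs(self.tumor_contrast_hu["noncontrast"])
        cv = abs(self.tumor_contrast_hu["venous"])
        if not cv > cnc:
            # the generator's defining premise: lesions are conspicuous with
            # contrast and subtle without it
            raise ConfigurationError(
                f"venous |contrast| ({cv}) must exceed non-contrast |contrast| ({cnc})")

    @classmethod
    def tiny(cls, **overrides) -> "PhantomConfig":
        """Desk-scale preset: 64 px field of view (48 mm at 0.75 mm spacing),
        diameters rescaled so lesions fit while all three strata occur."""
        kwargs = dict(image_size=64,
                      diameter_dist=DiameterDist(16.0, 8.0, 3.2, 30.0))
        kwargs.update(overrides)
        return cls(**kwargs)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_tumor_diameters(config: PhantomConfig, n: int, rng=None) -> np.ndarray:
    """Draw ``n`` lesion diameters (mm) from the truncated normal."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    d = config.diameter_dist
    if n == 0:
        return np.empty(0)
    rng = _rng(config.seed if rng is None else rng)
    a = (d.min_mm - d.mean_mm) / d.sd_mm
    b = (d.max_mm - d.mean_mm) / d.sd_mm
    return stats.truncnorm.rvs(a, b, loc=d.mean_mm, scale=d.sd_mm, size=n, random_state=rng)


def _smooth_texture(rng, shape, sd, sigma=3.0):
    if sd == 0:
        return np.zeros(shape)
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=sigma)
    s = tex.std()
    return tex * (sd / s) if s > 0 else tex


def generate_case(config: PhantomConfig, seed, n_slices: int = 1,
                  diameters=None) -> PhantomCase:
    """Generate one paired-phase case with shared anatomy.

    ``seed`` may be an int or a sequence of ints (so datasets can derive
    independent per-case streams); identical config + seed gives
    bit-identical output. ``n_slices`` > 1 produces a thin 3-D stack with
    ellipsoidal lesions (used for resampling and distance tests).
    ``diameters`` overrides the sampled nominal diameters (mm).
    """
    rng = _rng(seed)
    S = config.image_size
    sp_r, sp_c = config.pixel_spacing_mm
    if n_slices > 1:
        shape = (n_slices, S, S)
        spacing = (config.slice_thickness_mm, sp_r, sp_c)
    else:
        shape = (S, S)
        spacing = (sp_r, sp_c)
    size_mm = np.asarray(shape) * np.asarray(spacing)
    coords = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                         indexing="ij")

    texture = _smooth_texture(rng, shape, config.liver_texture_sd_hu)

    if diameters is None:
        diameters = sample_tumor_diameters(config, config.n_tumors_per_slice, rng=rng)
    mask = np.zeros(shape, dtype=bool)
    records = []
    for d_nominal in diameters:
        placed = False
        for _ in range(_MAX_PLACEMENT_RETRIES):
            ecc = rng.uniform(*config.eccentricity_range)
            semi = np.full(len(shape), d_nominal / 2.0)
            # shrink one in-plane axis; which one is chosen at random
            minor_axis = len(shape) - 1 - int(rng.integers(2))
            semi[minor_axis] = d_nominal / (2.0 * ecc)
            if len(shape) == 3:
                # thin-stack mode: cap the through-plane semi-axis so the
                # lesion fits; in-plane extent still sets the diameter
                semi[0] = min(semi[0], size_mm[0] / 2.0 - 2.0 * spacing[0])
            margin = semi + np.asarray(spacing)
            if np.any(2 * margin >= size_mm):
                continue  # cannot fit at this eccentricity/orientation
            center = np.array([rng.uniform(m, s - m) for m, s in zip(margin, size_mm)])
            comp = sum(((c - ctr) / sa) ** 2
                       for c, ctr, sa in zip(coords, center, semi)) <= 1.0
            if not comp.any() or (comp & mask).any():
                continue
            mask |= comp
            measured = max_diameter_mm(comp, spacing)
            records.append(TumorRecord(tuple(center), measured,
                                       stratum_of(measured), float(d_nominal)))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {d_nominal:.1f} mm lesion in a "
                f"{size_mm} mm field of view after {_MAX_PLACEMENT_RETRIES} tries")

    anatomy = config.liver_hu + texture
    volumes = {}
    for phase in ("noncontrast", "venous"):
        img = anatomy + config.tumor_contrast_hu[phase] * mask
        if config.noise_sd_hu > 0:
            img = img + rng.normal(0.0, config.noise_sd_hu, size=shape)
        volumes[phase] = CTVolume(img, spacing, phase)

    return PhantomCase(volumes["noncontrast"], volumes["venous"],
                       mask.astype(np.uint8), records)


def split_sizes(n_cases: int, fractions) -> list:
    """Partition ``n_cases`` by fractions; later splits are floored and the
    first split absorbs the remainder (so 654 at 80/10/10 -> 524/65/65)."""
    fr = np.asarray(fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ConfigurationError(f"split fractions must sum to 1, got {fr.tolist()}")
    rest = [int(np.floor(f * n_cases)) for f in fr[1:]]
    sizes = [n_cases - sum(rest)] + rest
    if any(s < 1 for s, f in zip(sizes, fr) if f > 0):
        raise ConfigurationError(
            f"n_cases={n_cases} too small for split fractions {fr.tolist()}")
    return sizes


def generate_dataset(config: PhantomConfig, n_cases: int,
                     split=(0.8, 0.1, 0.1), seed=None) -> dict:
    """Generate a disjoint train/val/test dict of :class:`PhantomCase`."""
    seed = config.seed if seed is None else seed
    sizes = split_sizes(n_cases, split)
    cases = []
    for i in range(n_cases):
        case = generate_case(config, seed=[int(seed), i])
        case.case_id = f"case_{i:04d}"
        cases.append(case)
    order = _rng([int(seed), n_cases]).permutation(n_cases)
    out, start = {}, 0
    for name, size in zip(("train", "val", "test"), sizes):
        out[name] = [cases[j] for j in order[start:start + size]]
        start += size
    return out


# -- persistence ---------------------------------------------------------

def _affine(spacing3):
    return np.diag(list(spacing3) + [1.0])


def write_case_nifti(case: PhantomCase, outdir) -> None:
    """Write the two phases + mask as .nii.gz with spacing in the header."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, data, spacing in (
        ("noncontrast", case.noncontrast.data, case.noncontrast.spacing),
        ("venous", case.venous.data, case.venous.spacing),
        ("mask", case.mask, case.noncontrast.spacing),
    ):
        arr = np.asarray(data)
        sp = list(spacing)
        if arr.ndim == 2:  # single slice: store as 1-thick volume
            arr = arr[None]
            sp = [1.5] + sp
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(sp))
        nib.save(img, outdir / f"{case.case_id or 'case'}_{name}.nii.gz")


def manifest(cases) -> pd.DataFrame:
    rows = []
    for case in cases:
        for t, rec in enumerate(case.tumor_records):
            rows.append({
                "case_id": case.case_id, "tumor": t,
                "center_mm": ";".join(f"{c:.2f}" for c in rec.center_mm),
                "diameter_mm": rec.diameter_mm,
                "nominal_diameter_mm": rec.nominal_diameter_mm,
                "stratum": rec.stratum,
            })
    return pd.DataFrame(rows, columns=["case_id", "tumor", "center_mm",
                                       "diameter_mm", "nominal_diameter_mm", "stratum"])


def save_npz(cases, path) -> None:
    """Compact single-file bundle of many cases (for quick reload)."""
    arrays = {}
    for i, c in enumerate(cases):
        arrays[f"nc_{i}"] = c.noncontrast.data
        arrays[f"ven_{i}"] = c.venous.data
        arrays[f"mask_{i}"] = c.mask
        arrays[f"spacing_{i}"] = np.asarray(c.noncontrast.spacing)
    arrays["n"] = np.asarray(len(cases))
    np.savez_compressed(path, **arrays)


def load_npz(path) -> list:
    with np.load(path) as z:
        n = int(z["n"])
        cases = []
        for i in range(n):
            sp = tuple(z[f"spacing_{i}"])
            cases.append(PhantomCase(
                CTVolume(z[f"nc_{i}"], sp, "noncontrast"),
                CTVolume(z[f"ven_{i}"], sp, "venous"),
                z[f"mask_{i}"].astype(np.uint8), [], case_id=f"case_{i:04d}"))
        return cases


def config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "diameter_dist" in d and isinstance(d["diameter_dist"], dict):
        d["diameter_dist"] = DiameterDist(**d["diameter_dist"])
    if "pixel_spacing_mm" in d:
        d["pixel_spacing_mm"] = tuple(d["pixel_spacing_mm"])
    if "eccentricity_range" in d:
        d["eccentricity_range"] = tuple(d["eccentricity_range"])
    return PhantomConfig(**d)
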