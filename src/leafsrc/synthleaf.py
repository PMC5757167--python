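"""Deterministic synthetic leaf-shape generator.

Shapes are radial Fourier contours

    r(theta) = r0 * (1 + sum_k a_k cos(k theta + phi_k)
                       + tooth_depth * cos(tooth_freq * theta)),

rasterized as filled silhouettes with the major axis vertical (an aspect
factor shrinks the horizontal semi-axis).  Low-order harmonics span the
classical leaf-shape taxonomy — elliptic, linear, cordate, lobed — and a
high-frequency low-amplitude term produces dentate (toothed) margins.

The hierarchy mimics how real leaf collections vary:

* a *family* is a fixed parameter set (the prototype / typical shape);
* a *species* is a family plus a species-level random excursion of the
  harmonic spectrum (distinct species of one family share the gross shape
  but differ in fine contour detail);
* a *sample* is a species plus small relative noise on every amplitude, a
  random in-plane rotation, and optionally an attached footstalk.

Randomness is hierarchical: every (family, species, sample) triple gets its
own generator derived from the root seed through a fixed spawn key, so
adding species or samples never shifts earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from skimage.draw import polygon

from .imaging import PreprocessConfig, preprocess
from .partition import RepresentativeSet, TrainingSet

__all__ = [
    "ShapeFamily",
    "SynthSpec",
    "FAMILY_LIBRARY",
    "render_prototype",
    "render_sample",
    "sample_dataset",
    "default_benchmark",
]


class GenerationError(ValueError):
    """Raised when shape parameters yield a degenerate (self-intersecting)
    contour even after bounded resampling."""


@dataclass
class ShapeFamily:
    """Parametric contour family.

    harmonics maps harmonic order k to (amplitude, phase); aspect is the
    vertical/horizontal semi-axis ratio (>= 1: major axis vertical)."""

    name: str
    aspect: float = 1.5
    harmonics: dict = field(default_factory=dict)
    tooth_freq: int = 0
    tooth_depth: float = 0.0
    notch_depth: float = 0.0  # basal sinus (cordate/obcordate), at theta = 0
    notch_width: float = 0.25  # angular sd of the sinus, radians
    id: int = -1

    def amplitude_sum(self) -> float:
        return sum(abs(a) for a, _ in self.harmonics.values()) + abs(self.tooth_depth)


# Typical-shape library, ordered so the leading entries are maximally
# distinct: these are the default representative shapes.  Every family
# carries a first-harmonic (base-vs-apex) asymmetry, as real leaves do;
# it also anchors the 180-degree orientation of the aligned raster.
FAMILY_LIBRARY: list[ShapeFamily] = [
    ShapeFamily("elliptic", aspect=1.8, harmonics={1: (0.18, 0.0)}, id=0),
    ShapeFamily(
        "cordate",
        aspect=1.3,
        harmonics={1: (0.22, 0.0), 2: (0.15, 0.0)},
        notch_depth=0.45,
        notch_width=0.30,
        id=1,
    ),
    ShapeFamily("lobed-3", aspect=1.5, harmonics={3: (0.20, 0.0), 1: (0.18, 0.0)}, id=2),
    ShapeFamily("lobed-7", aspect=1.4, harmonics={7: (0.18, 0.0), 1: (0.20, 0.0)}, id=3),
    ShapeFamily(
        "dentate", aspect=1.6, harmonics={1: (0.18, 0.0)}, tooth_freq=24, tooth_depth=0.06, id=4
    ),
    ShapeFamily("linear", aspect=5.0, harmonics={1: (0.18, 0.0)}, id=5),
    ShapeFamily("oblong", aspect=3.0, harmonics={1: (0.18, 0.0), 2: (0.05, 0.0)}, id=6),
    ShapeFamily("orbicular", aspect=1.08, harmonics={1: (0.18, 0.0)}, id=7),
]

# species-level spectrum excursion: sd of the additive amplitude draw at
# each of the perturbed harmonic orders, and relative sd on the aspect.
# Only low orders (2..4) are perturbed: order 1 anchors the raster
# orientation and orders >= 5 carry the lobed family signatures.
SPECIES_AMP_SD = 0.02
SPECIES_ASPECT_SD = 0.08
SPECIES_NOTCH_SD = 0.2
SPECIES_HARMONICS = (2, 3, 4)


@dataclass
class SynthSpec:
    """Study-condition knobs of the generator.

    noise is the relative standard deviation applied to every harmonic
    amplitude (and aspect) per sample — the within-species shape variation.
    """

    n_families: int = 4
    species_per_family: int = 3
    samples_per_species: int = 20
    noise: float = 0.05
    rotation_range: float = 180.0
    stalk: bool = False
    stalk_width: int = 3
    stalk_length: int = 40
    seed: int = 7
    size: int = 160
    preprocess_cfg: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self):
        if min(self.n_families, self.species_per_family, self.samples_per_species) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")
        if self.n_families > len(FAMILY_LIBRARY):
            raise ValueError(f"at most {len(FAMILY_LIBRARY)} families available")


def default_benchmark() -> SynthSpec:
    """The package's standard desk-scale benchmark: 4 shape families x
    3 species x 20 samples at 5% within-species noise, seed 7."""
    return SynthSpec()


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _contour_radius(fam: ShapeFamily, theta: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    for k, (amp, phase) in fam.harmonics.items():
        r += amp * np.cos(k * theta + phase)
    if fam.tooth_freq:
        r += fam.tooth_depth * np.cos(fam.tooth_freq * theta)
    if fam.notch_depth:
        wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
        r -= fam.notch_depth * np.exp(-(wrapped**2) / (2.0 * fam.notch_width**2))
    return r


def _render(
    fam: ShapeFamily,
    size: int,
    rotation_deg: float = 0.0,
    stalk: Optional[tuple[int, int]] = None,
    n_theta: int = 720,
    intensity: float = 200.0,
) -> np.ndarray:
    """Rasterize the filled contour (plus optional stalk) at the given
    rotation.  Raises GenerationError if the radius goes nonpositive."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rel = _contour_radius(fam, theta)
    if rel.min() <= 0.05:
        raise GenerationError(
            f"family {fam.name!r}: contour radius collapses (min {rel.min():.3f})"
        )
    pad = stalk[1] if stalk else 0
    canvas = size + 2 * pad
    c0 = canvas / 2.0
    r0 = 0.42 * size / (1.0 + fam.amplitude_sum())
    rows = rel * r0 * np.cos(theta)
    cols = rel * r0 * np.sin(theta) / fam.aspect

    polys = [(rows, cols)]
    if stalk is not None:
        w, length = stalk
        tip = rel[0] * r0  # contour point at theta = 0 (bottom of the blade)
        half = w / 2.0
        srows = np.array([tip - 2.0, tip + length, tip + length, tip - 2.0])
        scols = np.array([-half, -half, half, half])
        polys.append((srows, scols))

    phi = np.radians(rotation_deg)
    cphi, sphi = np.cos(phi), np.sin(phi)
    img = np.zeros((canvas, canvas))
    for prows, pcols in polys:
        rr = cphi * prows - sphi * pcols + c0
        cc = sphi * prows + cphi * pcols + c0
        fr, fc = polygon(rr, cc, shape=img.shape)
        img[fr, fc] = intensity
    return img


def render_prototype(fam: ShapeFamily, size: int = 160) -> np.ndarray:
    """Noise-free filled silhouette of the family prototype, major axis
    vertical, background zero.  Deterministic."""
    return _render(fam, size)


def _perturb_species(fam: ShapeFamily, rng: np.random.Generator) -> ShapeFamily:
    harmonics = {k: (a, p) for k, (a, p) in fam.harmonics.items()}
    for k in SPECIES_HARMONICS:
        amp0, phase0 = harmonics.get(k, (0.0, float(rng.uniform(0.0, 2.0 * np.pi))))
        harmonics[k] = (amp0 + float(rng.normal(0.0, SPECIES_AMP_SD)), phase0)
    aspect = fam.aspect * float(np.exp(rng.normal(0.0, SPECIES_ASPECT_SD)))
    notch = fam.notch_depth * float(np.exp(rng.normal(0.0, SPECIES_NOTCH_SD)))
    return replace(fam, harmonics=harmonics, aspect=max(aspect, 1.0), notch_depth=notch)


def _perturb_sample(fam: ShapeFamily, noise: float, rng: np.random.Generator) -> ShapeFamily:
    harmonics = {
        k: (a * (1.0 + float(rng.normal(0.0, noise))), p)
        for k, (a, p) in fam.harmonics.items()
    }
    aspect = max(fam.aspect * (1.0 + float(rng.normal(0.0, noise))), 1.0)
    depth = fam.tooth_depth * (1.0 + float(rng.normal(0.0, noise)))
    notch = fam.notch_depth * (1.0 + float(rng.normal(0.0, noise)))
    return replace(fam, harmonics=harmonics, aspect=aspect, tooth_depth=depth, notch_depth=notch)


def render_sample(
    species_fam: ShapeFamily, spec: SynthSpec, rng: np.random.Generator
) -> np.ndarray:
    """One raw synthetic leaf photograph of the given species: perturbed
    shape, random rotation, optional stalk.  Degenerate perturbations are
    resampled a bounded number of times."""
    rotation = float(rng.uniform(0.0, spec.rotation_range)) if spec.rotation_range else 0.0
    stalk = (spec.stalk_width, spec.stalk_length) if spec.stalk else None
    for _ in range(5):
        fam = _perturb_sample(species_fam, spec.noise, rng)
        try:
            return _render(fam, spec.size, rotation_deg=rotation, stalk=stalk)
        except GenerationError:
            continue
    raise GenerationError(
        f"species of family {species_fam.name!r}: no valid contour after 5 resamples"
    )


def sample_dataset(
    spec: SynthSpec, test_per_species: int = 0
) -> dict:
    """Generate a complete labelled dataset, preprocessed to contour rasters.

    Returns {'train': TrainingSet, 'test': TrainingSet | None,
    'reps': RepresentativeSet, 'truth': list} where `reps` holds the
    noise-free family prototypes run through the same preprocessing chain,
    and `truth` are the test labels.  Fully reproducible from spec.seed.
    """
    families = FAMILY_LIBRARY[: spec.n_families]
    reps_rasters = [
        preprocess(render_prototype(f, spec.size), spec.preprocess_cfg, source_id=f.name)
        for f in families
    ]
    reps = RepresentativeSet(reps_rasters, [f.name for f in families])

    def _make(split_tag: int, count: int) -> TrainingSet | None:
        if count == 0:
            return None
        rasters, labels = [], []
        for fi, fam in enumerate(families):
            for si in range(spec.species_per_family):
                sp_rng = _rng(spec.seed, 1, fi, si)
                species_fam = _perturb_species(fam, sp_rng)
                name = f"{fam.name}-{si}"
                for xi in range(count):
                    rng = _rng(spec.seed, split_tag, fi, si, xi)
                    img = render_sample(species_fam, spec, rng)
                    sid = f"{name}-{'t' if split_tag == 3 else 'x'}{xi}"
                    rasters.append(preprocess(img, spec.preprocess_cfg, source_id=sid))
                    labels.append(name)
        return TrainingSet(rasters, labels)

    train = _make(2, spec.samples_per_species)
    test = _make(3, test_per_species)
    return {
        "train": train,
        "test": test,
        "reps": reps,
        "truth": list(test.species) if test is not None else [],
    }
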