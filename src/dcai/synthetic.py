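"""Synthetic nodule generator: paired 32^3 cubes and 9x4 rating matrices.

Emulates the preprocessed real cohort so the full pipeline is exercisable
without CT data.  Benign nodules are smooth soft spheres; malignant nodules
are larger, have irregular, spiculated margins (radial spikes), and shifted
ordinal ratings on the malignancy-associated attributes (spiculation,
lobulation, margin, diameter).  A single separation knob ``delta`` scales
every class difference: ``delta = 0`` produces a null dataset whose
class-conditional distributions are identical; ``delta = 1`` is the default
clearly-separable regime.

The class signal is injected into both modalities but attenuated
independently per modality and per sample (uniform on [0.15, 1]), so either
modality alone misses some cases that the other one catches — the property
that makes multimodal fusion worth testing, not just classification.

All randomness flows through one seeded generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ingest import ATTRIBUTE_NAMES, ORDINAL_RANGES, RatingMatrix
from .train import Dataset

CUBE = 32


@dataclass
class SynthConfig:
    n_samples: int = 684
    malignant_fraction: float = 330.0 / 684.0
    delta: float = 1.0          # class-separation strength in [0, 1]
    sigma: float = 0.05         # additive Gaussian image noise (intensity units)
    reader_jitter: float = 0.7  # per-reader rating noise, ordinal steps
    attenuation_lo: float = 0.15  # per-sample per-modality signal attenuation
    seed: int = 0


# class-conditional latent means per attribute (benign baseline); the
# malignant shift below is scaled by delta and the per-sample attenuation
_BENIGN_MEANS = {
    "subtlety": 3.0, "internal_structure": 1.2, "calcification": 4.0,
    "sphericity": 4.0, "margin": 4.2, "lobulation": 1.8, "spiculation": 1.5,
    "texture": 4.0, "diameter": 8.0,
}
_MALIGNANT_SHIFTS = {
    "spiculation": 2.0, "lobulation": 2.0, "margin": -1.8, "diameter": 8.0,
}

_BASE_RADIUS = 6.0       # mm; benign sphere radius
_RADIUS_GAIN = 3.0       # extra malignant radius at full signal
_SPIKE_AMPLITUDE = 0.6   # fractional radius modulation of spiculation spikes
_N_SPIKES = 6
_NODULE_INTENSITY = 0.55
_BACKGROUND = 0.15
_EDGE_SOFTNESS = 0.8     # mm; sigmoid width of the nodule boundary

# precomputed voxel grid (centre of the cube is the nodule centre)
_coords = np.arange(CUBE) - (CUBE - 1) / 2.0
_ZZ, _YY, _XX = np.meshgrid(_coords, _coords, _coords, indexing="ij")
_DIST = np.sqrt(_ZZ ** 2 + _YY ** 2 + _XX ** 2)
with np.errstate(invalid="ignore"):
    _DIRS = np.stack([_ZZ, _YY, _XX], axis=-1) / _DIST[..., None]
_DIRS[_DIST == 0] = 0.0


def _attenuation(cfg: SynthConfig, rng: np.random.Generator) -> float:
    return float(rng.uniform(cfg.attenuation_lo, 1.0))


def gen_cube(label: int, config: SynthConfig, rng: np.random.Generator,
             attenuation: float | None = None) -> np.ndarray:
    """One 32^3 cube in [0, 1]; malignant cubes get a larger radius and
    delta-scaled radial spikes with an irregular boundary."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    att = _attenuation(config, rng) if attenuation is None else attenuation
    signal = config.delta * att * label
    radius = _BASE_RADIUS + _RADIUS_GAIN * signal
    # spike directions are drawn for both classes so that delta = 0 yields
    # identical generative code paths (amplitude is simply zero)
    spikes = rng.standard_normal((_N_SPIKES, 3))
    spikes /= np.linalg.norm(spikes, axis=1, keepdims=True)
    cos = np.clip(_DIRS @ spikes.T, 0.0, None)  # (32,32,32,K)
    spike_field = (cos ** 8).max(axis=-1)
    # small random boundary irregularity on top of the coherent spikes
    wobble = rng.standard_normal(3)
    irregular = 0.15 * (_DIRS @ wobble)
    r_eff = radius * (1.0 + signal * (_SPIKE_AMPLITUDE * spike_field + irregular))
    body = 1.0 / (1.0 + np.exp(-(r_eff - _DIST) / _EDGE_SOFTNESS))
    cube = _BACKGROUND + _NODULE_INTENSITY * body
    cube += config.sigma * rng.standard_normal(cube.shape)
    return np.clip(cube, 0.0, 1.0)


def gen_ratings(label: int, config: SynthConfig, rng: np.random.Generator,
                attenuation: float | None = None) -> RatingMatrix:
    """One 9x4 ordinal rating matrix with per-reader jitter.

    Malignant shifts apply to spiculation, lobulation, margin and diameter,
    scaled by delta and the per-sample attenuation.  Diameter is a single
    per-nodule value replicated across the four reader columns, matching the
    real-cohort matrix layout.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    att = _attenuation(config, rng) if attenuation is None else attenuation
    signal = config.delta * att * label
    values = np.empty((len(ATTRIBUTE_NAMES), 4))
    for i, name in enumerate(ATTRIBUTE_NAMES):
        mean = _BENIGN_MEANS[name] + signal * _MALIGNANT_SHIFTS.get(name, 0.0)
        lo, hi = ORDINAL_RANGES[name]
        if name == "diameter":
            dia = mean + config.reader_jitter * rng.standard_normal()
            values[i, :] = np.clip(dia, max(lo, 3.0), hi)
        else:
            row = mean + config.reader_jitter * rng.standard_normal(4)
            values[i, :] = np.clip(np.rint(row), lo, hi)
    return RatingMatrix(values)


def gen_dataset(config: SynthConfig) -> tuple[Dataset, pd.DataFrame]:
    """A full labeled dataset plus its manifest.

    The requested prevalence is met exactly (n_malignant = round(n *
    malignant_fraction)); sample order is shuffled.  The manifest records
    the generator config so a run is reconstructible from it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_mal = int(round(n * config.malignant_fraction))
    labels = np.array([1] * n_mal + [0] * (n - n_mal), dtype=np.intp)
    rng.shuffle(labels)
    ratings = np.empty((n, 9, 4))
    cubes = np.empty((n, CUBE, CUBE, CUBE))
    for i, label in enumerate(labels):
        # independent attenuations: a sample can be obvious on imaging yet
        # equivocal on ratings, and vice versa
        att_img = _attenuation(config, rng)
        att_tab = _attenuation(config, rng)
        cubes[i] = gen_cube(int(label), config, rng, attenuation=att_img)
        ratings[i] = gen_ratings(int(label), config, rng,
                                 attenuation=att_tab).values
    ids = [f"synth{i:05d}" for i in range(n)]
    dataset = Dataset(ratings, cubes, labels, ids)
    manifest = pd.DataFrame({"nodule_id": ids, "label": labels})
    for key, val in asdict(config).items():
        manifest[f"config_{key}"] = val
    return dataset, manifest
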