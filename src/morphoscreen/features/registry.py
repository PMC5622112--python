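"""The fixed, versioned 548-feature registry.

The profile is partitioned, in this immutable order, into

* geometry    — indices 1-43   (13 shape scalars + 30 Zernike magnitudes)
* granularity — indices 44-53  (10-scale granular spectrum)
* intensity   — indices 54-96  (43 intensity statistics)
* texture     — indices 97-548 (13 Haralick stats x 4 angles x 8 distances
                                + 4 x 9 Gabor energies = 452)

Indices are 1-based, matching the conventional "feature No." numbering.
Exact parity with any particular profiling tool's feature identities is not
claimed; the taxonomy and counts are the contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

SHAPE_NAMES = [
    "area",
    "perimeter",
    "form_factor",
    "solidity",
    "extent",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "orientation",
    "compactness",
    "equivalent_diameter",
    "feret_diameter_max",
    "feret_diameter_min",
]

#: (n, m) Zernike orders: n = 0..9, m of the same parity, 0 <= m <= n.
ZERNIKE_ORDERS = [(n, m) for n in range(10) for m in range(n % 2, n + 1, 2)]

GRANULARITY_SCALES = list(range(1, 11))

_STAT10 = [
    "integrated",
    "mean",
    "median",
    "std",
    "mad",
    "min",
    "max",
    "lower_quartile",
    "upper_quartile",
    "iqr",
]

HARALICK_NAMES = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
]

GLCM_DISTANCES = (1, 2, 3, 4, 5, 6, 8, 10)
GLCM_ANGLES = (0, 45, 90, 135)

GABOR_THETAS = (0, 45, 90, 135)
GABOR_WAVELENGTHS = (2, 3, 4, 6, 8, 12, 16, 24, 32)

N_GEOMETRY = 43
N_GRANULARITY = 10
N_INTENSITY = 43
N_TEXTURE = 452
N_FEATURES = N_GEOMETRY + N_GRANULARITY + N_INTENSITY + N_TEXTURE

CATEGORY_SLICES = {
    "geometry": slice(0, 43),
    "granularity": slice(43, 53),
    "intensity": slice(53, 96),
    "texture": slice(96, 548),
}


@dataclass(frozen=True)
class FeatureEntry:
    index: int  # 1-based registry index
    name: str
    category: str
    params: dict = field(default_factory=dict)


def _build_entries() -> list[FeatureEntry]:
    entries: list[FeatureEntry] = []

    def add(name: str, category: str, **params) -> None:
        entries.append(FeatureEntry(len(entries) + 1, name, category, params))

    for name in SHAPE_NAMES:
        add(f"geometry_{name}", "geometry")
    for n, m in ZERNIKE_ORDERS:
        add(f"geometry_zernike_{n}_{m}", "geometry", n=n, m=m)

    for s in GRANULARITY_SCALES:
        add(f"granularity_scale_{s}", "granularity", scale=s)

    for stat in _STAT10:
        add(f"intensity_{stat}", "intensity")
    for stat in _STAT10:
        add(f"intensity_edge_{stat}", "intensity")
    add("intensity_mass_displacement", "intensity")
    add("intensity_centroid_x", "intensity")
    add("intensity_centroid_y", "intensity")
    for r in range(1, 11):
        add(f"intensity_radial_mean_{r}", "intensity", ring=r)
    for r in range(1, 11):
        add(f"intensity_radial_cv_{r}", "intensity", ring=r)

    for d in GLCM_DISTANCES:
        for a in GLCM_ANGLES:
            for stat in HARALICK_NAMES:
                add(
                    f"texture_haralick_{stat}_d{d}_a{a}",
                    "texture",
                    distance=d,
                    angle=a,
                )
    for theta in GABOR_THETAS:
        for wl in GABOR_WAVELENGTHS:
            add(
                f"texture_gabor_energy_o{theta}_w{wl}",
                "texture",
                theta=theta,
                wavelength=wl,
            )
    return entries


FEATURE_REGISTRY: list[FeatureEntry] = _build_entries()

FEATURE_NAMES = [e.name for e in FEATURE_REGISTRY]
FEATURE_CATEGORIES = [e.category for e in FEATURE_REGISTRY]


def category_of(index: int) -> str:
    """Category of a 1-based registry index."""
    if not 1 <= index <= N_FEATURES:
        raise ValueError(f"index {index} outside 1..{N_FEATURES}")
    return FEATURE_REGISTRY[index - 1].category


def export_registry_json(path) -> None:
    """Write the registry as JSON (index, name, category, params)."""
    payload = [
        {"index": e.index, "name": e.name, "category": e.category, "params": e.params}
        for e in FEATURE_REGISTRY
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# Registry contract, checked at import time.
assert len(FEATURE_REGISTRY) == N_FEATURES
assert len(set(FEATURE_NAMES)) == N_FEATURES, "feature names must be unique"
assert [e.category for e in FEATURE_REGISTRY[0:43]] == ["geometry"] * 43
assert [e.category for e in FEATURE_REGISTRY[43:53]] == ["granularity"] * 10
assert [e.category for e in FEATURE_REGISTRY[53:96]] == ["intensity"] * 43
assert [e.category for e in FEATURE_REGISTRY[96:548]] == ["texture"] * 452
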