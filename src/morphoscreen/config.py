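"""Run configuration: one structured object drives the whole pipeline."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .synthetic import AcquisitionParams, DoseResponseModel


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run.

    The defaults are the emulated study conditions: negative control plus a
    10-fold dilution series 1 nM - 10 uM, durations 12 h and 24 h, two
    experimental repeats, and an effect that rises to a peak at 1 uM then
    rolls back at 10 uM.
    """

    # generator
    doses: tuple = (0.0, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5)
    ec50: float = 5e-8
    hill_k: float = 1.0
    peak_dose: float = 1e-6
    rollback_fraction: float = 0.35
    duration_scale: float = 0.6
    durations: tuple = (12, 24)
    experiments: tuple = (1, 2)
    n_per_condition: int = 1000
    seed: int = 0

    # acquisition (image path only)
    use_images: bool = False
    frame_height: int = 96
    frame_width: int = 96
    background_level: float = 0.15
    noise_sd: float = 0.01

    # analysis
    svm_c: float = 1.0
    folds: int = 10
    mmd_convention: str = "all-pairs"
    mmd_subsample: int = 2000
    retain_grid: tuple | None = None

    def model(self) -> DoseResponseModel:
        return DoseResponseModel(
            doses=tuple(self.doses),
            ec50=self.ec50,
            hill_k=self.hill_k,
            peak_dose=self.peak_dose,
            rollback_fraction=self.rollback_fraction,
            duration_scale=self.duration_scale,
        )

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(
            frame_height=self.frame_height,
            frame_width=self.frame_width,
            background_level=self.background_level,
            noise_sd=self.noise_sd,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("doses", "durations", "experiments"):
            d[key] = list(d[key])
        if d["retain_grid"] is not None:
            d["retain_grid"] = list(d["retain_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("doses", "durations", "experiments"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("retain_grid") is not None:
            d["retain_grid"] = tuple(d["retain_grid"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(config: RunConfig) -> list[str]:
    """Return human-readable findings; an empty list means the config is valid."""
    findings: list[str] = []
    if config.seed is None:
        findings.append("seed must be explicit (got None)")
    if config.n_per_condition < 2:
        findings.append(
            f"n_per_condition={config.n_per_condition} < 2: the unbiased MMD "
            "estimator requires m, n >= 2"
        )
    if 0.0 not in config.doses:
        findings.append("doses must include 0 (the negative control)")
    if config.peak_dose not in config.doses:
        findings.append(
            f"peak_dose {config.peak_dose:g} is not one of the configured doses "
            f"{sorted(config.doses)}"
        )
    for d in config.durations:
        if d not in (12, 24):
            findings.append(f"unknown duration {d}; valid durations are (12, 24)")
    if config.folds < 2:
        findings.append(f"folds={config.folds} < 2")
    if not 0.0 < config.duration_scale < 1.0:
        findings.append("duration_scale must be in (0, 1)")
    if config.retain_grid is not None:
        bad = [r for r in config.retain_grid if r < 1 or r > 548]
        if bad:
            findings.append(f"retain_grid values out of range 1..548: {bad}")
    if config.mmd_convention not in ("all-pairs", "printed"):
        findings.append(f"unknown MMD convention {config.mmd_convention!r}")
    return findings


def derive_seed(base: int, *parts) -> int:
    """Deterministic per-stage seed below 2^31, stable across platforms."""
    tag = ":".join(str(p) for p in (base, *parts))
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF
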