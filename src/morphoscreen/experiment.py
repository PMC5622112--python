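"""Closed-form bookkeeping of the emulated acquisition protocol."""

from __future__ import annotations


def mean_flow_speed(
    flow_rate_mL_per_min: float, width_m: float, height_m: float
) -> float:
    """Mean flow speed (m/s) of a volumetric rate through a rectangular
    microchannel cross-section.

    2.75 mL/min through 100 um x 44 um gives ~10 m/s.
    """
    if flow_rate_mL_per_min <= 0 or width_m <= 0 or height_m <= 0:
        raise ValueError("flow rate and channel dimensions must be positive")
    rate_m3_per_s = flow_rate_mL_per_min * 1e-6 / 60.0
    return rate_m3_per_s / (width_m * height_m)


def solvent_volume_fraction(stock_molar: float, final_molar: float) -> float:
    """Volume fraction of solvent carried into the final dilution.

    Diluting a 1 mM stock (drug dissolved in pure solvent) to 10 uM final
    implies a 1:100 dilution, i.e. 1% v/v solvent.
    """
    if stock_molar <= 0 or final_molar <= 0:
        raise ValueError("concentrations must be positive")
    if final_molar > stock_molar:
        raise ValueError("final concentration cannot exceed the stock")
    return final_molar / stock_molar


def dataset_size(
    images_per_condition: int,
    n_doses: int,
    n_controls: int = 1,
    n_durations: int = 2,
    n_repeats: int = 2,
) -> int:
    """Total image count: per-condition count x (controls + doses) x
    durations x repeats. 10,000 x (1 + 5) x 2 x 2 = 240,000."""
    if min(images_per_condition, n_doses, n_controls, n_durations, n_repeats) <= 0:
        raise ValueError("all counts must be positive")
    return images_per_condition * (n_controls + n_doses) * n_durations * n_repeats
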