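"""Published reference measurements of *E. coli* K-12 NCM3722 cell size.

Population-averaged length, width, projected area and volume (mean ± SD)
of steady-state cells grown in MOPS minimal medium with four different
sole carbon sources, quantified from the same phase-contrast image set
(> 4500 cells per condition) by three segmentation tools under different
settings:

* MicrobeJ with auto-threshold offset −200 and 100,
* Oufti with two cellwidth/meshwidth parameter sets (Set1, Set2),
* BacStalk at its default setting (reports the *maximum* cell width),
* custom deep-learning scripts (report a *fitted mean* cell width).

These numbers are the canonical demonstration that the same images yield
systematically different absolute — and, more importantly, different
*relative* — cell sizes depending on software and parameter settings.
They seed the synthetic population models and the setting-comparison
workflow in this package.
"""

from __future__ import annotations

import pandas as pd

from .geometry import SizeVector
from .synth import PopulationModel

__all__ = [
    "CONDITIONS",
    "SETTINGS",
    "GROWTH_RATES_PER_H",
    "GROWTH_RATE_SD_PER_H",
    "size_table",
    "size_vector",
    "population_models",
]

#: Growth conditions, ordered by increasing growth rate.
CONDITIONS = ("glutamine", "alanine", "glycerol", "glucose")

#: Quantification settings (tool + parameter set).
SETTINGS = (
    "microbej_-200",
    "microbej_100",
    "oufti_set1",
    "oufti_set2",
    "bacstalk",
    "custom",
)

#: Steady-state growth rate (h^-1) per carbon source.
GROWTH_RATES_PER_H = {
    "glutamine": 0.11,
    "alanine": 0.52,
    "glycerol": 0.65,
    "glucose": 0.93,
}

GROWTH_RATE_SD_PER_H = {
    "glutamine": 0.02,
    "alanine": 0.01,
    "glycerol": 0.02,
    "glucose": 0.06,
}

# feature -> condition -> per-setting (mean, sd), settings in SETTINGS order.
_TABLE = {
    "length_um": {
        "glutamine": [(1.85, 0.44), (2.16, 0.47), (2.03, 0.47), (2.04, 0.47), (2.25, 0.48), (2.11, 0.54)],
        "alanine":   [(2.22, 0.59), (2.51, 0.67), (2.38, 0.56), (2.38, 0.56), (2.63, 0.66), (2.35, 0.45)],
        "glycerol":  [(2.61, 0.67), (2.94, 0.72), (2.77, 0.65), (2.78, 0.64), (3.04, 0.69), (2.79, 0.88)],
        "glucose":   [(2.73, 0.65), (2.97, 0.68), (2.81, 0.67), (2.80, 0.66), (3.11, 0.67), (2.88, 0.60)],
    },
    "width_um": {
        "glutamine": [(0.55, 0.06), (0.75, 0.06), (0.52, 0.03), (0.55, 0.03), (0.79, 0.06), (0.55, 0.05)],
        "alanine":   [(0.61, 0.06), (0.81, 0.06), (0.57, 0.02), (0.57, 0.02), (0.83, 0.06), (0.60, 0.05)],
        "glycerol":  [(0.67, 0.08), (0.88, 0.08), (0.60, 0.03), (0.64, 0.03), (0.90, 0.07), (0.65, 0.05)],
        "glucose":   [(0.79, 0.08), (0.96, 0.08), (0.72, 0.04), (0.69, 0.03), (1.00, 0.07), (0.74, 0.06)],
    },
    "area_um2": {
        "glutamine": [(0.94, 0.26), (1.51, 0.37), (1.04, 0.25), (1.10, 0.27), (1.17, 0.26), (1.02, 0.22)],
        "alanine":   [(1.28, 0.36), (1.90, 0.54), (1.35, 0.33), (1.35, 0.33), (1.47, 0.36), (1.25, 0.24)],
        "glycerol":  [(1.66, 0.48), (2.46, 0.66), (1.64, 0.42), (1.74, 0.43), (1.86, 0.44), (1.60, 0.30)],
        "glucose":   [(2.03, 0.52), (2.70, 0.67), (2.00, 0.51), (1.92, 0.49), (2.13, 0.47), (1.90, 0.39)],
    },
    "volume_um3": {
        "glutamine": [(0.39, 0.13), (0.85, 0.24), (0.44, 0.11), (0.49, 0.13), (0.96, 0.25), (0.46, 0.13)],
        "alanine":   [(0.59, 0.19), (1.15, 0.37), (0.63, 0.16), (0.63, 0.16), (1.26, 0.36), (0.59, 0.12)],
        "glycerol":  [(0.85, 0.31), (1.62, 0.51), (0.80, 0.22), (0.90, 0.23), (1.74, 0.48), (0.84, 0.26)],
        "glucose":   [(1.21, 0.37), (1.92, 0.56), (1.18, 0.31), (1.09, 0.29), (2.18, 0.57), (1.11, 0.25)],
    },
}


def size_table() -> pd.DataFrame:
    """Reference size measurements as a tidy table.

    Columns: setting, condition, growth_rate_per_h, feature, mean, sd.
    """
    rows = []
    for feature, by_cond in _TABLE.items():
        for cond in CONDITIONS:
            for setting, (mean, sd) in zip(SETTINGS, by_cond[cond]):
                rows.append(
                    {
                        "setting": setting,
                        "condition": cond,
                        "growth_rate_per_h": GROWTH_RATES_PER_H[cond],
                        "feature": feature,
                        "mean": mean,
                        "sd": sd,
                    }
                )
    return pd.DataFrame(rows)


def size_vector(setting: str, condition: str) -> SizeVector:
    """Reference means/SDs for one setting and condition as a :class:`SizeVector`."""
    if setting not in SETTINGS:
        raise KeyError(f"unknown setting {setting!r}; choose from {SETTINGS}")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; choose from {CONDITIONS}")
    i = SETTINGS.index(setting)
    vals = {feat: _TABLE[feat][condition][i] for feat in _TABLE}
    return SizeVector(
        length_um=vals["length_um"][0],
        width_um=vals["width_um"][0],
        area_um2=vals["area_um2"][0],
        volume_um3=vals["volume_um3"][0],
        length_sd=vals["length_um"][1],
        width_sd=vals["width_um"][1],
        area_sd=vals["area_um2"][1],
        volume_sd=vals["volume_um3"][1],
        n=4500,
    )


def population_models(
    setting: str = "custom", lw_correlation: float = 0.3
) -> list[PopulationModel]:
    """Per-condition synthetic population models seeded from a reference setting.

    Length and width means/SDs come from the chosen setting's measurements;
    growth rates are the per-condition steady-state values.  The default
    setting is the fitted-mean-width one, whose width definition matches
    the generator's ground truth most directly.
    """
    models = []
    for cond in CONDITIONS:
        sv = size_vector(setting, cond)
        models.append(
            PopulationModel(
                condition_name=cond,
                length_mean_um=sv.length_um,
                length_sd_um=sv.length_sd,
                width_mean_um=sv.width_um,
                width_sd_um=sv.width_sd,
                lw_correlation=lw_correlation,
                growth_rate_per_h=GROWTH_RATES_PER_H[cond],
            )
        )
    return models
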