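"""Loaders for the packaged reference tables.

Three small tab-delimited files ship with the package:

* ``table1_country_structure.tsv`` — the published per-country summary of
  the 1990–91 twenty-country European dataset (region counts, mean/min/max
  region population, Gini coefficient, and the baseline-model within-country
  standard deviation).  The underlying region-level data were never
  deposited, so these country summaries are the only real numbers available
  and are used for descriptor-level checks and worked examples, never as
  model-fitting input.
* ``table2_model_comparison.tsv`` — the published coefficient estimates,
  95% credible intervals, significance stars and DIC values for the eleven
  variance-structure models fitted to that dataset.
* ``age_schedule.tsv`` — a synthetic male 0–64 age composition (14 bands)
  and age-specific all-cause death rates used as generator defaults; values
  are plausible for European males around 1990 but are a constructed
  schedule, not published data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_country_structure",
    "load_model_comparison",
    "load_age_schedule",
    "default_age_proportions",
    "default_reference_rates",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("geostruct.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_country_structure() -> pd.DataFrame:
    """The 20-country structure summary (one row per country)."""
    return _read("table1_country_structure.tsv")


def load_model_comparison() -> pd.DataFrame:
    """Published estimates and DICs for the 11 variance-structure models."""
    return _read("table2_model_comparison.tsv")


def load_age_schedule() -> pd.DataFrame:
    """Synthetic age composition and reference death rates (14 bands)."""
    return _read("age_schedule.tsv")


def default_age_proportions() -> np.ndarray:
    """Population share per age band; sums to 1."""
    return load_age_schedule()["proportion"].to_numpy(dtype=float)


def default_reference_rates() -> np.ndarray:
    """Death rate per person-year per age band."""
    return load_age_schedule()["rate"].to_numpy(dtype=float)
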