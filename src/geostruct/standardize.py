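"""Indirect standardisation of region–age death counts.

Age-banded counts are collapsed to one observed total O_ij and one expected
total E_ij per region.  Expected deaths apply age-specific reference rates
to the region's own age structure; the reference is the pooled table itself
(every region of every country), so the identity sum(E) = sum(O) holds
exactly and the overall standardised mortality ratio is 1.  log(E_ij) is
the offset of the Poisson variance-function models downstream.

The input is a tidy delimited table with columns
``country_id, region_id, age_band, population, deaths``.  Age bands are
indices 0–13 mapping to half-open intervals (0, 1-4, 5-9, ..., 60-64);
every region must carry a row for every band present in the table —
silently treating a missing band as zero population is refused.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import StandardizationError

__all__ = [
    "REQUIRED_COLUMNS",
    "AGE_BAND_LABELS",
    "read_table",
    "write_table",
    "validate_table",
    "pooled_reference_rates",
    "expected_deaths",
    "collapse_observed",
    "region_summaries",
    "write_summaries",
    "read_summaries",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["country_id", "region_id", "age_band", "population", "deaths"]

#: Half-open age intervals [lower, upper) for band indices 0-13.
AGE_BAND_LABELS = (
    "0", "1-4", "5-9", "10-14", "15-19", "20-24", "25-29",
    "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60-64",
)


def read_table(path) -> pd.DataFrame:
    """Read a region–age count table from tab-delimited text."""
    table = pd.read_csv(path, sep="\t")
    validate_table(table)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write a region–age count table as tab-delimited text."""
    table.to_csv(path, sep="\t", index=False)


def validate_table(table: pd.DataFrame) -> None:
    """Check structural invariants of a region–age count table.

    Raises :class:`StandardizationError` on duplicate (country, region,
    band) keys, negative counts, non-integer deaths, or a region missing
    one of the table's age bands.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise StandardizationError(f"table lacks required columns: {missing}")
    if table[["country_id", "region_id", "age_band"]].duplicated().any():
        raise StandardizationError("duplicate (country, region, age_band) rows")
    if (table["population"] < 0).any():
        raise StandardizationError("negative population")
    deaths = table["deaths"]
    if (deaths < 0).any():
        raise StandardizationError("negative deaths")
    if not np.allclose(deaths, np.round(deaths)):
        raise StandardizationError("death counts must be integers")
    bands = set(table["age_band"].unique())
    band_counts = table.groupby(["country_id", "region_id"])["age_band"].nunique()
    short = band_counts[band_counts < len(bands)]
    if not short.empty:
        key = short.index[0]
        raise StandardizationError(
            f"region {key} is missing age-band rows ({short.iloc[0]} of "
            f"{len(bands)}); absent bands must be explicit rows"
        )


def pooled_reference_rates(table: pd.DataFrame) -> pd.Series:
    """Age-specific death rates of the pooled (all-region) population.

    Returns a Series indexed by age band: pooled deaths / pooled exposure.
    """
    validate_table(table)
    grouped = table.groupby("age_band")[["population", "deaths"]].sum()
    empty = grouped.index[grouped["population"] <= 0]
    if len(empty) > 0:
        raise StandardizationError(
            f"age band(s) {list(empty)} have zero pooled population; "
            "reference rate undefined"
        )
    rates = grouped["deaths"] / grouped["population"]
    rates.name = "rate"
    return rates


def expected_deaths(table: pd.DataFrame, rates: pd.Series) -> pd.Series:
    """Per-region expected deaths E_ij = sum_bands population x reference rate."""
    validate_table(table)
    rate_per_row = table["age_band"].map(rates)
    if rate_per_row.isna().any():
        band = table.loc[rate_per_row.isna(), "age_band"].iloc[0]
        raise StandardizationError(f"no reference rate for age band {band}")
    expected = (table["population"] * rate_per_row).groupby(
        [table["country_id"], table["region_id"]], sort=False
    ).sum()
    expected.name = "expected"
    return expected


def collapse_observed(table: pd.DataFrame) -> pd.Series:
    """Per-region observed deaths O_ij summed over age bands (integer)."""
    validate_table(table)
    observed = table.groupby(["country_id", "region_id"], sort=False)["deaths"].sum()
    observed = observed.round().astype(int)
    observed.name = "observed"
    return observed


def region_summaries(
    table: pd.DataFrame, rates: pd.Series | None = None
) -> pd.DataFrame:
    """Observed, expected and SMR per region, in stable input order.

    ``rates`` defaults to the internal pooled reference (the table itself);
    supplying external rates is allowed for experimentation and is flagged
    in the log.  Regions with E = 0 cannot contribute a log offset and are
    dropped with a warning.
    """
    if rates is None:
        rates = pooled_reference_rates(table)
    else:
        logger.warning("using externally supplied reference rates, not the "
                       "internal pooled reference")
    observed = collapse_observed(table)
    expected = expected_deaths(table, rates)
    out = pd.DataFrame({"observed": observed, "expected": expected}).reset_index()
    zero = out["expected"] <= 0
    if zero.any():
        for _, row in out[zero].iterrows():
            logger.warning(
                "dropping region (%s, %s): expected deaths are zero",
                row["country_id"], row["region_id"],
            )
        out = out[~zero].reset_index(drop=True)
    out["smr"] = out["observed"] / out["expected"]
    return out


def write_summaries(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", index=False)


def read_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
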