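"""Interpretation of fitted variance-function models, and the pipeline.

The fitted quantities are translated into the scales practitioners read:

* the percent excess of the standardised mortality ratio at an upper
  centile of the region distribution over the matching lower centile
  implied by a within-country SD sigma on the log scale
  (``100 (exp((z_p - z_{1-p}) sigma) - 1)``),
* the proportional change in sigma_u(j) per covariate change implied by a
  log-link slope (``100 (exp(beta delta) - 1)``), and
* the absolute change ``beta delta`` implied by a linear-link slope.

:func:`run_pipeline` chains simulate -> standardize -> structure -> fit ->
report, writing every intermediate artifact plus a manifest with the seed
and a config hash so a rerun is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import sys

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import DomainError, GeostructError
from . import standardize, structure
from .model import MCMCConfig, ModelData, fit_all_variants, make_model_spec
from .simulate import SimulationConfig, generate_dataset

__all__ = [
    "excess_between_centiles",
    "pct_change_log_model",
    "abs_change_linear_model",
    "build_country_table",
    "interpretation_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def excess_between_centiles(sigma: float, p: float = 0.95) -> float:
    """Percent excess SMR of a notional region at centile ``p`` over one at
    ``1 - p``, for a log-scale region-level SD ``sigma``.

    With region effects u ~ N(0, sigma^2), the SMR ratio between the p-th
    and (1-p)-th centiles is exp((z_p - z_{1-p}) sigma); returned as a
    percentage, e.g. sigma 0.07 at p 0.95 gives about 26%.
    """
    if sigma < 0:
        raise DomainError("sigma must be nonnegative")
    if not (0.5 < p < 1.0):
        raise DomainError("upper centile p must lie in (0.5, 1)")
    span = ndtri(p) - ndtri(1.0 - p)
    return 100.0 * (np.exp(span * sigma) - 1.0)


def pct_change_log_model(beta: float, delta: float) -> float:
    """Percent change in sigma_u(j) per covariate change ``delta`` under a
    log-link structure: 100 (exp(beta delta) - 1)."""
    if not (np.isfinite(beta) and np.isfinite(delta)):
        raise DomainError("beta and delta must be finite")
    return 100.0 * (np.exp(beta * delta) - 1.0)


def abs_change_linear_model(beta: float, delta: float) -> float:
    """Absolute change in sigma_u(j) (SD units) under a linear-link
    structure: beta * delta."""
    if not (np.isfinite(beta) and np.isfinite(delta)):
        raise DomainError("beta and delta must be finite")
    return beta * delta


def build_country_table(table: pd.DataFrame, model1_fit=None) -> pd.DataFrame:
    """Country-summary report: region count, mean/min/max population, Gini,
    and (when a baseline random-model fit is supplied) the posterior median
    within-country SD sigma_u(j)."""
    out = structure.country_structure_table(table)
    if model1_fit is not None:
        su = model1_fit.sigma_u_summary.set_index("country_id")["median"]
        out["sigma_u_median"] = out["country_id"].map(su)
    return out


def interpretation_report(
    comparison: pd.DataFrame,
    fits: dict,
    structure_table: pd.DataFrame,
    delta_gini: float = 0.1,
    delta_size: float = 0.5,
    p: float = 0.95,
) -> dict:
    """Assemble the interpretable quantities from a set of fitted variants.

    All numbers are pure functions of the stored fit summaries, so
    regenerating the report from the same fits is byte-identical.
    """
    report: dict = {
        "delta_gini": delta_gini,
        "delta_size_millions": delta_size,
        "centile": p,
    }
    dic = comparison[["variant", "description", "dic", "converged"]].copy()
    dic = dic.sort_values("dic", kind="stable").reset_index(drop=True)
    report["dic_ranking"] = dic.to_dict(orient="records")

    per_model = []
    for v, fit in sorted(fits.items()):
        spec = fit.spec
        entry: dict = {"variant": v, "description": spec.description}
        if spec.link == "log":
            if spec.use_gini:
                entry["pct_change_per_delta_gini"] = pct_change_log_model(
                    fit.param_median("beta2"), delta_gini
                )
            if spec.use_size:
                entry["pct_change_per_delta_size"] = pct_change_log_model(
                    fit.param_median("beta3"), delta_size
                )
        elif spec.link == "linear":
            if spec.use_gini:
                entry["abs_change_per_delta_gini"] = abs_change_linear_model(
                    fit.param_median("beta2"), delta_gini
                )
            if spec.use_size:
                entry["abs_change_per_delta_size"] = abs_change_linear_model(
                    fit.param_median("beta3"), delta_size
                )
        per_model.append(entry)
    report["proportional_changes"] = per_model

    baseline = fits.get(1)
    if baseline is not None:
        excess = {
            row["country_id"]: excess_between_centiles(row["median"], p)
            for _, row in baseline.sigma_u_summary.iterrows()
        }
        report["excess_at_centiles_pct"] = excess
        med = baseline.sigma_u_summary["median"]
        report["sigma_u_range"] = [float(med.min()), float(med.max())]
        report["excess_range_pct"] = [
            excess_between_centiles(float(med.min()), p),
            excess_between_centiles(float(med.max()), p),
        ]

    if structure_table is not None and len(structure_table) >= 3:
        r, pval = structure.weighted_pearson(
            structure_table["gini"],
            structure_table["mean_pop"],
            structure_table["n_regions"],
        )
        report["weighted_correlation"] = {"r": r, "p": pval}
    return report


def _config_hash(config: SimulationConfig) -> str:
    import dataclasses

    raw = dataclasses.asdict(config)
    for key, val in raw.items():
        if isinstance(val, np.ndarray):
            raw[key] = val.tolist()
        elif isinstance(val, tuple):
            raw[key] = list(val)
    blob = json.dumps(raw, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    variants=(1, 3),
    mcmc: MCMCConfig | None = None,
    seed: int | None = None,
) -> pathlib.Path:
    """simulate -> standardize -> structure -> fit -> report, with artifacts.

    Every intermediate is written as delimited text under ``out_dir``; a
    manifest records package version, seeds and the config hash.  A stage
    failure aborts with the stage name, leaving earlier artifacts intact.
    """
    from . import __version__

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        import dataclasses

        config = dataclasses.replace(config, seed=seed)
    if mcmc is None:
        mcmc = MCMCConfig.desk(seed=config.seed)

    stage = "simulate"
    try:
        table, truth = generate_dataset(config)
        standardize.write_table(table, out / "region_age_table.tsv")
        truth.to_json(out / "truth.json")

        stage = "standardize"
        summaries = standardize.region_summaries(table)
        standardize.write_summaries(summaries, out / "region_summaries.tsv")

        stage = "structure"
        struct_table = structure.country_structure_table(table)
        struct_table.to_csv(out / "country_structure.tsv", sep="\t", index=False)

        stage = "fit"
        data = ModelData.from_frames(summaries, struct_table)
        comparison, fits = fit_all_variants(data, variants, mcmc)
        comparison.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
        for v, fit in fits.items():
            fit.save(out / "chains", prefix=f"variant{v}")

        stage = "report"
        report = interpretation_report(comparison, fits, struct_table)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        country_table = build_country_table(table, fits.get(1))
        country_table.to_csv(out / "country_table.tsv", sep="\t", index=False)
    except Exception as exc:
        raise GeostructError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package": "geostruct",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "mcmc": {
            "n_chains": mcmc.n_chains,
            "burn_in": mcmc.effective_burn_in,
            "n_keep": mcmc.effective_keep,
            "thin": mcmc.thin,
            "seed": mcmc.seed,
        },
        "variants": list(variants),
        "config_sha256": _config_hash(config),
        "artifacts": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
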