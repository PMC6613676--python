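"""End-to-end convenience layer: records -> biomarkers -> effects -> AUC.

These helpers chain the library stages exactly as the command-line interface
does: biomarker extraction per record, heart-rate correction fitted on
drug-free data, replicate averaging, single/double deltas joined to drug
concentrations, exposure-response effect profiles, and group I / group II
discrimination observations.
"""

from __future__ import annotations

import pandas as pd

from .core import records_to_table
from .discrimination import BlockDiscriminationModel, DiscriminationResult
from .exposure_response import (
    TRXC_PARAMETERS,
    EffectProfile,
    double_delta,
    effect_profile,
    single_delta,
)
from .rate_correction import RateCorrectionModel, RateCorrectionResults, drug_free_subset


def biomarker_table(records, **kwargs) -> pd.DataFrame:
    """Wide per-record biomarker table (Tr10..Tr100, RR, QT, QTcF)."""
    return records_to_table(records, **kwargs)


def rate_corrected_table(table: pd.DataFrame,
                         placebo: str = "Placebo",
                         baseline_time: float = 0.0
                         ) -> tuple[pd.DataFrame, RateCorrectionResults]:
    """Fit the RR mixed model on drug-free rows and append TrXc columns."""
    drug_free = drug_free_subset(table, placebo=placebo,
                                 baseline_time=baseline_time)
    results = RateCorrectionModel(drug_free).fit()
    return results.correct(table), results


def double_delta_table(corrected: pd.DataFrame, pk_table: pd.DataFrame,
                       treatment: str, drugs: list[str],
                       parameters=TRXC_PARAMETERS,
                       extra_parameters=("QTcF",),
                       placebo: str = "Placebo",
                       baseline_time: float = 0.0,
                       pool_treatments: list[str] | None = None) -> pd.DataFrame:
    """ddP rows for one treatment (optionally pooled with other periods),
    joined to per-drug concentrations (zero where a drug was not dosed)."""
    params = [p for p in list(parameters) + list(extra_parameters)
              if p in corrected.columns]
    arms = [treatment] + list(pool_treatments or [])
    sub = corrected[corrected["treatment"].isin(arms + [placebo])]
    deltas = single_delta(sub, params, baseline_time=baseline_time)
    dd = double_delta(deltas, params, placebo=placebo)
    for drug in drugs:
        conc = pk_table[pk_table["drug"] == drug]
        dd = dd.merge(
            conc[["subject_id", "treatment", "nominal_time_h", "concentration"]]
            .rename(columns={"concentration": f"C_{drug}"}),
            on=["subject_id", "treatment", "nominal_time_h"], how="left",
        )
        dd[f"C_{drug}"] = dd[f"C_{drug}"].fillna(0.0)
    return dd


def treatment_effect_profile(corrected: pd.DataFrame, pk_table: pd.DataFrame,
                             treatment: str, drugs: list[str], rep_conc,
                             parameters=TRXC_PARAMETERS,
                             include_interaction: bool = False,
                             pool_treatments: list[str] | None = None,
                             n_boot: int = 2000, seed: int = 0,
                             placebo: str = "Placebo",
                             baseline_time: float = 0.0) -> EffectProfile:
    """Drug effect profile for one treatment arm (or pooled combination)."""
    dd = double_delta_table(corrected, pk_table, treatment, drugs,
                            parameters=parameters, placebo=placebo,
                            baseline_time=baseline_time,
                            pool_treatments=pool_treatments)
    profile = effect_profile(
        dd, rep_conc=rep_conc, conc_cols=[f"C_{d}" for d in drugs],
        parameters=parameters, include_interaction=include_interaction,
        n_boot=n_boot, seed=seed,
    )
    profile.metadata.update({"treatment": treatment, "drugs": list(drugs)})
    return profile


def discrimination_observations(corrected: pd.DataFrame,
                                group1_treatments: list[str],
                                group2_treatments: list[str],
                                parameters=TRXC_PARAMETERS,
                                extra_parameters=("QTcF",),
                                placebo: str = "Placebo",
                                baseline_time: float = 0.0) -> pd.DataFrame:
    """Labelled ddP observations: group I (pure hERG) = 0, group II = 1.

    Uses all post-dose subject x timepoint double deltas of the named arms;
    pre-dose rows are excluded by the baseline differencing itself.
    """
    params = [p for p in list(parameters) + list(extra_parameters)
              if p in corrected.columns]
    frames = []
    for label, arms in ((0, group1_treatments), (1, group2_treatments)):
        sub = corrected[corrected["treatment"].isin(list(arms) + [placebo])]
        deltas = single_delta(sub, params, baseline_time=baseline_time)
        dd = double_delta(deltas, params, placebo=placebo)
        dd["label"] = label
        frames.append(dd)
    return pd.concat(frames, ignore_index=True)


def discrimination_aucs(observations: pd.DataFrame,
                        n_boot: int = 2000, seed: int = 0
                        ) -> dict[str, DiscriminationResult]:
    """AUC per single ddTrXc feature, for ddQTcF, and the all-quantile model."""
    out: dict[str, DiscriminationResult] = {}
    single = [c for c in observations.columns
              if c.startswith("ddTr") and c.endswith("c")]
    for col in single:
        out[col] = BlockDiscriminationModel(observations, [col]).fit(
            n_boot=n_boot, seed=seed)
    if "ddQTcF" in observations.columns:
        out["ddQTcF"] = BlockDiscriminationModel(observations, ["ddQTcF"]).fit(
            n_boot=n_boot, seed=seed)
    if len(single) > 1:
        out["all_TrXc"] = BlockDiscriminationModel(observations, single).fit(
            n_boot=n_boot, seed=seed)
    return out
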