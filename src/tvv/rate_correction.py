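"""Heart-rate correction of the trajectory quantiles.

Repolarization times lengthen with the beat interval, so each parameter
TrX is regressed on RR in a linear mixed-effects model with per-subject
random intercepts and slopes,

    TrX ~ 1 + RR + (1 + RR | subject),

fitted by REML on drug-free data only (placebo-arm records plus the
pre-dose baselines of every arm).  The fixed slope beta (ms per ms of RR)
defines the corrected value

    TrXc = TrX - beta * (RR - 1000),

anchored so that correction is the identity at RR = 1000 ms.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

logger = logging.getLogger(__name__)

DEFAULT_PARAMETERS = tuple(f"Tr{x}" for x in range(10, 101, 10))
RR_ANCHOR_MS = 1000.0


def apply_rate_correction(trx_ms, rr_ms, beta: float):
    """TrXc = TrX - beta * (RR - 1000); exact identity at RR = 1000 ms."""
    return np.asarray(trx_ms, dtype=float) - beta * (np.asarray(rr_ms, dtype=float) - RR_ANCHOR_MS)


def _fit_mixed_rr(endog: np.ndarray, rr: np.ndarray, groups: np.ndarray,
                  reml: bool = True) -> tuple[dict, bool]:
    """Random intercept+slope fit; falls back to independent random effects.

    Returns (parameter dict, fell_back flag).  RR is centred at the 1000 ms
    anchor and standardized for numerical stability of the variance
    optimization; estimates are reported on the raw ms scale (the intercept
    is the population value at RR = 1000 ms).  The fallback drops the
    random-effect covariance (diagonal structure) when the full fit fails
    to converge or is singular.
    """
    sd = float(np.std(rr))
    if sd <= 0:
        raise ValueError("RR has no variation; cannot fit a rate model")
    z = (rr - RR_ANCHOR_MS) / sd
    exog = sm.add_constant(z)
    model = MixedLM(endog, exog, groups=groups, exog_re=exog)

    def _extract(res):
        cov_re = np.asarray(res.cov_re)
        return {
            "intercept": float(res.fe_params[0]),
            "beta": float(res.fe_params[1]) / sd,
            "beta_se": float(res.bse_fe[1]) / sd,
            "re_var_intercept": float(cov_re[0, 0]),
            "re_var_slope": float(cov_re[1, 1]) / sd ** 2,
            "re_cov": float(cov_re[0, 1]) / sd,
            "resid_var": float(res.scale),
        }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml)
            singular = (not res.converged) or np.linalg.cond(np.asarray(res.cov_re)) > 1e8
            if not singular and np.isfinite(_extract(res)["beta_se"]):
                return _extract(res), False
        except (np.linalg.LinAlgError, ValueError):
            pass
        free = MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2)
        )
        res = model.fit(free=free, reml=reml)
    out = _extract(res)
    out["re_cov"] = 0.0
    return out, True


@dataclass
class RateCorrectionResults:
    """Fitted heart-rate dependence per parameter.

    ``params_`` maps parameter name to the fit summary (intercept, beta,
    beta SE, random-effect variances); ``beta(name)`` gives the slope used
    by :meth:`correct`.
    """

    params_: dict[str, dict]
    n_subjects: int
    n_observations: int
    method: str = "reml"
    fallbacks: dict[str, bool] = field(default_factory=dict)

    def beta(self, parameter: str) -> float:
        return self.params_[parameter]["beta"]

    def correct(self, table: pd.DataFrame, rr_col: str = "RR",
                suffix: str = "c") -> pd.DataFrame:
        """Append heart-rate-corrected columns ``<parameter>c`` to a wide table."""
        out = table.copy()
        for name, p in self.params_.items():
            if name in out.columns:
                out[name + suffix] = apply_rate_correction(
                    out[name].to_numpy(float), out[rr_col].to_numpy(float), p["beta"]
                )
        return out

    def summary(self) -> str:
        lines = [
            "Heart-rate correction (TrX ~ 1 + RR + (1 + RR | subject), "
            f"{self.method.upper()})",
            f"subjects: {self.n_subjects}   observations: {self.n_observations}",
            f"{'parameter':<10}{'beta (ms/ms)':>14}{'SE':>10}{'intercept':>12}"
            f"{'fallback':>10}",
        ]
        for name, p in self.params_.items():
            lines.append(
                f"{name:<10}{p['beta']:>14.5f}{p['beta_se']:>10.5f}"
                f"{p['intercept']:>12.2f}{str(self.fallbacks.get(name, False)):>10}"
            )
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "params": self.params_, "n_subjects": self.n_subjects,
            "n_observations": self.n_observations, "method": self.method,
            "fallbacks": self.fallbacks,
        }, indent=1)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "RateCorrectionResults":
        from pathlib import Path
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") else str(source)
        d = json.loads(text)
        return cls(params_=d["params"], n_subjects=d["n_subjects"],
                   n_observations=d["n_observations"], method=d.get("method", "reml"),
                   fallbacks=d.get("fallbacks", {}))


class RateCorrectionModel:
    """Mixed-effects heart-rate dependence model for trajectory quantiles.

    Parameters
    ----------
    data : wide DataFrame with one row per (drug-free) record, containing
        the subject column, the RR column (ms) and one column per parameter.
    parameters : parameter columns to fit (default Tr10..Tr100 present in data).
    """

    def __init__(self, data: pd.DataFrame, parameters=None,
                 subject_col: str = "subject_id", rr_col: str = "RR") -> None:
        if parameters is None:
            parameters = [p for p in DEFAULT_PARAMETERS if p in data.columns]
            parameters += [p for p in ("QT",) if p in data.columns]
        if not parameters:
            raise ValueError("no parameter columns found to fit")
        n_subjects = data[subject_col].nunique()
        if n_subjects < 2:
            raise ValueError(f"need at least 2 subjects, got {n_subjects}")
        self.data = data
        self.parameters = list(parameters)
        self.subject_col = subject_col
        self.rr_col = rr_col

    @classmethod
    def from_long(cls, long: pd.DataFrame, subject_col: str = "subject_id",
                  rr_col: str = "RR", parameter_col: str = "parameter",
                  value_col: str = "value", **kwargs) -> "RateCorrectionModel":
        """Build from a long table of (subject, RR, parameter, value) rows."""
        idx = [c for c in (subject_col, "treatment", "nominal_time_h", "replicate",
                           rr_col) if c in long.columns]
        wide = long.pivot_table(index=idx, columns=parameter_col,
                                values=value_col).reset_index()
        return cls(wide, subject_col=subject_col, rr_col=rr_col, **kwargs)

    def fit(self, method: str = "reml") -> RateCorrectionResults:
        reml = method.lower() == "reml"
        params: dict[str, dict] = {}
        fallbacks: dict[str, bool] = {}
        for name in self.parameters:
            sub = self.data[[self.subject_col, self.rr_col, name]].dropna()
            per_subject_rr = sub.groupby(self.subject_col)[self.rr_col].nunique()
            if (per_subject_rr < 2).any():
                logger.warning("parameter %s: some subjects have <2 distinct RR values",
                               name)
            fitted, fell_back = _fit_mixed_rr(
                sub[name].to_numpy(float), sub[self.rr_col].to_numpy(float),
                sub[self.subject_col].to_numpy(), reml=reml,
            )
            if fell_back:
                logger.info("parameter %s: singular random-effect covariance, "
                            "refit with independent random effects", name)
            if not np.isfinite(fitted["beta"]):
                raise RuntimeError(f"non-finite slope estimate for {name}")
            params[name] = fitted
            fallbacks[name] = fell_back
        return RateCorrectionResults(
            params_=params,
            n_subjects=int(self.data[self.subject_col].nunique()),
            n_observations=int(len(self.data)),
            method=method.lower(),
            fallbacks=fallbacks,
        )


def drug_free_subset(table: pd.DataFrame, placebo: str = "Placebo",
                     treatment_col: str = "treatment",
                     time_col: str = "nominal_time_h",
                     baseline_time: float = 0.0) -> pd.DataFrame:
    """All placebo-arm rows plus the pre-dose baselines of every arm."""
    mask = (table[treatment_col] == placebo) | (table[time_col] == baseline_time)
    return table.loc[mask]
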