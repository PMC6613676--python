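"""Placebo-corrected drug-effect estimation from exposure-response models.

Workflow: replicate ECGs are averaged per subject x treatment x timepoint;
the change from the pre-dose baseline is the single delta

    dP(t, TR) = P(t, TR) - P(t0, TR),

and the placebo-corrected change from baseline the double delta

    ddP(t, Drug) = dP(t, Drug) - dP(t, Placebo),

matched within subject and nominal time.  The concentration dependence is a
no-intercept linear mixed model with per-subject random slopes,

    ddP ~ 0 + C + (0 + C | subject)                      (one drug)
    ddP ~ 0 + C1 + C2 + C1:C2 + (0 + (C1 + C2) | subject)  (two drugs),

which forces the regression line or plane through the origin: a drug-free
record predicts exactly zero effect.  The model prediction at a
representative concentration, per quantile Tr10c..Tr100c with a
subject-resampling bootstrap CI, constitutes the drug effect profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

logger = logging.getLogger(__name__)

TRXC_PARAMETERS = tuple(f"Tr{x}c" for x in range(10, 101, 10))


def geometric_mean_concentration(values) -> float:
    """exp(mean(log(values))); zero/negative entries are excluded with a log."""
    arr = np.asarray(list(values), dtype=float)
    positive = arr[arr > 0]
    n_dropped = len(arr) - len(positive)
    if n_dropped:
        logger.info("geometric mean: excluded %d non-positive concentration(s)",
                    n_dropped)
    if len(positive) == 0:
        raise ValueError("geometric mean requires at least one positive value")
    return float(np.exp(np.mean(np.log(positive))))


def replicate_average(table: pd.DataFrame, value_cols,
                      subject_col: str = "subject_id",
                      treatment_col: str = "treatment",
                      time_col: str = "nominal_time_h") -> pd.DataFrame:
    """Average the replicate ECG values per subject x treatment x timepoint."""
    keys = [subject_col, treatment_col, time_col]
    return table.groupby(keys, as_index=False)[list(value_cols)].mean()


def single_delta(table: pd.DataFrame, value_cols,
                 baseline_time: float = 0.0,
                 subject_col: str = "subject_id",
                 treatment_col: str = "treatment",
                 time_col: str = "nominal_time_h",
                 average_replicates: bool = True) -> pd.DataFrame:
    """Change from the treatment period's pre-dose baseline, per parameter.

    Rows without a matching baseline are excluded with a logged reason.
    Replicates are averaged first unless the table is already averaged.
    """
    value_cols = list(value_cols)
    if average_replicates:
        table = replicate_average(table, value_cols, subject_col, treatment_col,
                                  time_col)
    base = table[table[time_col] == baseline_time]
    post = table[table[time_col] != baseline_time]
    merged = post.merge(
        base[[subject_col, treatment_col] + value_cols],
        on=[subject_col, treatment_col], how="left", suffixes=("", "_base"),
    )
    missing = merged[value_cols[0] + "_base"].isna()
    if missing.any():
        for _, row in merged.loc[missing, [subject_col, treatment_col]].drop_duplicates().iterrows():
            logger.warning("single delta: no baseline for subject=%s treatment=%s; "
                           "rows excluded", row[subject_col], row[treatment_col])
        merged = merged.loc[~missing]
    out = merged[[subject_col, treatment_col, time_col]].copy()
    for col in value_cols:
        out["d" + col] = merged[col] - merged[col + "_base"]
    return out


def double_delta(delta_table: pd.DataFrame, value_cols,
                 placebo: str = "Placebo",
                 subject_col: str = "subject_id",
                 treatment_col: str = "treatment",
                 time_col: str = "nominal_time_h") -> pd.DataFrame:
    """Placebo-corrected single deltas, matched within subject and time.

    The placebo arm may itself be passed as the "drug" (self-comparison
    gives identically zero), and rows lacking a placebo match are excluded
    with a logged reason.
    """
    dcols = ["d" + c for c in value_cols]
    pla = delta_table[delta_table[treatment_col] == placebo]
    drug = delta_table[delta_table[treatment_col] != placebo]
    if drug.empty:  # placebo vs itself
        drug = pla
    merged = drug.merge(
        pla[[subject_col, time_col] + dcols],
        on=[subject_col, time_col], how="left", suffixes=("", "_pla"),
    )
    missing = merged[dcols[0] + "_pla"].isna()
    if missing.any():
        logger.warning("double delta: %d row(s) without placebo match excluded",
                       int(missing.sum()))
        merged = merged.loc[~missing]
    out = merged[[subject_col, treatment_col, time_col]].copy()
    for col in value_cols:
        out["dd" + col] = merged["d" + col] - merged["d" + col + "_pla"]
    return out


# ---------------------------------------------------------------------------
# Concentration-effect mixed model
# ---------------------------------------------------------------------------

def _fit_no_intercept_lmm(endog, exog, exog_re, groups, reml=True,
                          start_params=None, allow_fallback=True):
    """Fit the no-intercept LMM, falling back to diagonal random effects.

    Returns (fe_params, bse_fe, params_object, fell_back).  ``start_params``
    warm-starts the variance optimization (used by the bootstrap).
    """
    model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    k_re = exog_re.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, start_params=start_params)
            if not allow_fallback:
                # bootstrap path: a boundary fit (zero random-effect
                # variance) is a legitimate estimate; reject only
                # non-finite results
                fe = np.asarray(res.fe_params)
                if not np.all(np.isfinite(fe)):
                    raise RuntimeError("non-finite fixed effects")
                return fe, np.asarray(res.bse_fe), res.params_object, False
            singular = (not res.converged) or (
                k_re > 1 and np.linalg.cond(np.asarray(res.cov_re)) > 1e8
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            if not allow_fallback:
                raise RuntimeError(str(exc)) from exc
            res, singular = None, True
        if singular:
            free = MixedLMParams.from_components(
                fe_params=np.ones(exog.shape[1]), cov_re=np.eye(k_re)
            )
            res = model.fit(free=free, reml=reml)
            return (np.asarray(res.fe_params), np.asarray(res.bse_fe),
                    res.params_object, True)
    return (np.asarray(res.fe_params), np.asarray(res.bse_fe),
            res.params_object, False)

@dataclass
class ExposureResponseResults:
    """Fitted no-intercept concentration-effect model for one parameter.

    ``slopes`` maps fixed-effect term (e.g. "C", "C1", "C1:C2") to its
    estimate; ``predict`` evaluates the fixed-effect response at given
    concentrations and is exactly zero at zero concentration.
    """

    slopes: dict[str, float]
    slope_se: dict[str, float]
    conc_cols: list[str]
    include_interaction: bool
    n_subjects: int
    n_observations: int
    fell_back: bool = False

    def predict(self, conc) -> float:
        c = np.atleast_1d(np.asarray(conc, dtype=float))
        if len(c) != len(self.conc_cols):
            raise ValueError(f"expected {len(self.conc_cols)} concentration(s)")
        val = sum(self.slopes[col] * c[i] for i, col in enumerate(self.conc_cols))
        if self.include_interaction and len(c) == 2:
            val += self.slopes[f"{self.conc_cols[0]}:{self.conc_cols[1]}"] * c[0] * c[1]
        return float(val)

    def summary(self) -> str:
        terms = ", ".join(f"{k}={v:.4g} (SE {self.slope_se[k]:.2g})"
                          for k, v in self.slopes.items())
        return (f"Exposure-response (no intercept, random slopes by subject): {terms}; "
                f"{self.n_subjects} subjects, {self.n_observations} obs"
                + ("; diagonal RE fallback" if self.fell_back else ""))


class ExposureResponseModel:
    """Concentration-effect mixed model for one double-delta endpoint.

    Parameters
    ----------
    data : DataFrame with one row per subject x timepoint, containing the
        endpoint column, one or two concentration columns and the subject
        column.
    value_col : the ddP endpoint column.
    conc_cols : one column (single drug) or two (drug combination).
    include_interaction : add the C1:C2 product term (two drugs only).
    """

    def __init__(self, data: pd.DataFrame, value_col: str, conc_cols,
                 include_interaction: bool = False,
                 subject_col: str = "subject_id") -> None:
        conc_cols = list(conc_cols)
        if len(conc_cols) not in (1, 2):
            raise ValueError("one or two concentration columns required")
        if include_interaction and len(conc_cols) != 2:
            raise ValueError("interaction requires two concentration columns")
        sub = data[[subject_col, value_col] + conc_cols].dropna()
        if sub[subject_col].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        if np.allclose(sub[conc_cols].to_numpy(float), 0.0):
            raise ValueError("all concentrations are zero; no exposure to model")
        self.data = sub
        self.value_col = value_col
        self.conc_cols = conc_cols
        self.include_interaction = include_interaction
        self.subject_col = subject_col

    def _design(self):
        """Standardized design matrices; slopes scale back via ``back``."""
        exog_cols = list(self.conc_cols)
        raw = self.data[self.conc_cols].to_numpy(float)
        # standardize concentrations for the variance optimization; slopes
        # are reported back on the raw concentration scale
        scales = np.array([s if s > 0 else 1.0
                           for s in np.sqrt(np.mean(raw ** 2, axis=0))])
        exog = raw / scales
        back = list(scales)
        if self.include_interaction:
            exog = np.column_stack([exog, exog[:, 0] * exog[:, 1]])
            exog_cols.append(f"{self.conc_cols[0]}:{self.conc_cols[1]}")
            back.append(scales[0] * scales[1])
        return exog, raw / scales, exog_cols, np.asarray(back)

    def fit(self, method: str = "reml") -> ExposureResponseResults:
        reml = method.lower() == "reml"
        exog, exog_re, exog_cols, back = self._design()
        endog = self.data[self.value_col].to_numpy(float)
        groups = self.data[self.subject_col].to_numpy()
        fe, bse, _, fell_back = _fit_no_intercept_lmm(endog, exog, exog_re,
                                                      groups, reml=reml)
        slopes = {col: float(fe[i]) / back[i] for i, col in enumerate(exog_cols)}
        slope_se = {col: float(bse[i]) / back[i] for i, col in enumerate(exog_cols)}
        if not all(np.isfinite(v) for v in slopes.values()):
            raise RuntimeError("non-finite slope estimate")
        return ExposureResponseResults(
            slopes=slopes, slope_se=slope_se, conc_cols=self.conc_cols,
            include_interaction=self.include_interaction,
            n_subjects=int(self.data[self.subject_col].nunique()),
            n_observations=int(len(self.data)), fell_back=fell_back,
        )


def fit_exposure_response(dd_table: pd.DataFrame, value_col: str, conc_cols,
                          include_interaction: bool = False,
                          subject_col: str = "subject_id",
                          method: str = "reml") -> ExposureResponseResults:
    """Convenience wrapper: build and fit an :class:`ExposureResponseModel`."""
    return ExposureResponseModel(dd_table, value_col, conc_cols,
                                 include_interaction, subject_col).fit(method)


# ---------------------------------------------------------------------------
# Drug effect profile
# ---------------------------------------------------------------------------

@dataclass
class EffectProfile:
    """Per-quantile drug effect at a representative concentration with 95% CI.

    ``table`` has one row per parameter with columns estimate, ci_lo, ci_hi
    (ms).  ``rep_conc`` echoes the concentration(s) the profile was
    evaluated at.
    """

    table: pd.DataFrame
    rep_conc: tuple
    n_boot: int
    n_failed: int = 0
    metadata: dict = field(default_factory=dict)

    def estimate(self, parameter: str) -> float:
        return float(self.table.set_index("parameter").loc[parameter, "estimate"])

    def ci(self, parameter: str) -> tuple[float, float]:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["ci_lo"]), float(row["ci_hi"])

    def covers(self, parameter: str, value: float) -> bool:
        lo, hi = self.ci(parameter)
        return lo <= value <= hi

    def summary(self) -> str:
        conc = ", ".join(f"{c:g}" for c in self.rep_conc)
        lines = [f"Drug effect profile at concentration ({conc}); "
                 f"{self.n_boot} bootstrap replicates ({self.n_failed} failed)",
                 f"{'parameter':<10}{'effect (ms)':>12}{'95% CI':>22}"]
        for _, row in self.table.iterrows():
            lines.append(f"{row['parameter']:<10}{row['estimate']:>12.2f}"
                         f"     [{row['ci_lo']:>7.2f}, {row['ci_hi']:>7.2f}]")
        return "\n".join(lines)


def effect_profile(dd_table: pd.DataFrame, rep_conc, conc_cols,
                   parameters=TRXC_PARAMETERS,
                   include_interaction: bool = False,
                   n_boot: int = 2000, seed: int = 0,
                   subject_col: str = "subject_id",
                   method: str = "reml") -> EffectProfile:
    """Drug effect profile with subject-resampling bootstrap CIs.

    Point estimates come from the full-data fits; the 95% CI per parameter
    is the percentile interval over ``n_boot`` cluster-bootstrap replicates
    (subjects resampled with replacement, all models refitted).  Replicates
    whose fit fails are dropped and counted; more than 10% failures raises
    a warning.
    """
    rep_conc = tuple(np.atleast_1d(np.asarray(rep_conc, dtype=float)))
    parameters = [p for p in parameters if "dd" + p in dd_table.columns]
    if not parameters:
        raise ValueError("no double-delta parameter columns found")
    reml = method.lower() == "reml"
    needed = ["dd" + p for p in parameters] + list(conc_cols) + [subject_col]
    clean = dd_table.dropna(subset=needed).reset_index(drop=True)

    # shared standardized design across parameters; the representative
    # concentration expressed on the same standardized scale
    ref_model = ExposureResponseModel(clean, "dd" + parameters[0], conc_cols,
                                      include_interaction, subject_col)
    exog, exog_re, exog_cols, back = ref_model._design()
    scaled_conc = np.asarray(rep_conc) / back[:len(rep_conc)]
    design_row = list(scaled_conc)
    if include_interaction:
        design_row.append(scaled_conc[0] * scaled_conc[1])
    design_row = np.asarray(design_row)
    groups_full = clean[subject_col].to_numpy()
    endogs = {p: clean["dd" + p].to_numpy(float) for p in parameters}

    point: dict[str, float] = {}
    warm: dict[str, object] = {}
    for p in parameters:
        fe, _, params_obj, _ = _fit_no_intercept_lmm(
            endogs[p], exog, exog_re, groups_full, reml=reml)
        point[p] = float(fe @ design_row)
        warm[p] = params_obj

    rng = np.random.default_rng(seed)
    subjects = np.asarray(sorted(clean[subject_col].unique()))
    subj_rows = {s: np.flatnonzero(groups_full == s) for s in subjects}
    boot: dict[str, list[float]] = {p: [] for p in parameters}
    n_failed = 0
    for _ in range(n_boot):
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([subj_rows[s] for s in draw])
        g = np.concatenate([
            np.full(len(subj_rows[s]), i) for i, s in enumerate(draw)
        ])
        try:
            vals = {}
            for p in parameters:
                fe, _, _, _ = _fit_no_intercept_lmm(
                    endogs[p][idx], exog[idx], exog_re[idx], g, reml=reml,
                    start_params=warm[p], allow_fallback=False)
                vals[p] = float(fe @ design_row)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for p in parameters:
            boot[p].append(vals[p])
    if n_boot and n_failed > 0.1 * n_boot:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap replicates failed",
                      stacklevel=2)
    rows = []
    for p in parameters:
        draws = np.asarray(boot[p])
        if len(draws):
            lo, hi = np.percentile(draws, [2.5, 97.5])
        else:
            lo = hi = point[p]
        # the interval always brackets the full-data point estimate
        rows.append({"parameter": p, "estimate": point[p],
                     "ci_lo": float(min(lo, point[p])),
                     "ci_hi": float(max(hi, point[p]))})
    return EffectProfile(
        table=pd.DataFrame(rows), rep_conc=rep_conc, n_boot=n_boot,
        n_failed=n_failed,
        metadata={"conc_cols": list(conc_cols),
                  "include_interaction": include_interaction, "seed": seed},
    )
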