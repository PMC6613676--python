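"""Discrimination of pure hERG/iKr block from multichannel block.

Observations are placebo-corrected changes from baseline (ddTrXc, ddQTcF,
optionally externally measured ddJ-Tpeakc) at post-dose timepoints, labelled
group I (pure outward-potassium block) or group II (additional inward-current
block).  A maximum-likelihood logistic regression on one or more features
yields per-observation scores; separation is summarized by the area under
the ROC curve with a stratified (within-class) bootstrap percentile CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

GROUP_PURE_HERG = 0   # group I
GROUP_MULTICHANNEL = 1  # group II


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie); ties receive half credit
    through midranks.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


@dataclass
class DiscriminationResult:
    """AUC of one feature set with a stratified-bootstrap 95% CI."""

    features: list[str]
    auc: float
    ci_lo: float
    ci_hi: float
    n_boot: int
    n_pos: int
    n_neg: int
    scores: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (f"AUC {self.auc:.3f} [{self.ci_lo:.3f}, {self.ci_hi:.3f}] "
                f"(features: {', '.join(self.features)}; "
                f"n = {self.n_neg}+{self.n_pos}; {self.n_boot} stratified "
                "bootstrap replicates)")


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                     features=("score",)) -> DiscriminationResult:
    """Stratified bootstrap percentile CI for the AUC.

    Observations are resampled with replacement within each class, so every
    replicate retains both classes; the 95% interval is the 2.5/97.5
    percentile of the replicate AUCs.  Deterministic under ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = roc_auc(scores, labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    ones = np.ones(len(pos), dtype=int)
    zeros = np.zeros(len(neg), dtype=int)
    lab = np.concatenate([ones, zeros])
    for i in range(n_boot):
        sample = np.concatenate([
            rng.choice(pos, size=len(pos), replace=True),
            rng.choice(neg, size=len(neg), replace=True),
        ])
        aucs[i] = roc_auc(sample, lab)
    lo, hi = np.percentile(aucs, [2.5, 97.5]) if n_boot else (point, point)
    return DiscriminationResult(
        features=list(features), auc=point,
        ci_lo=float(min(lo, point)), ci_hi=float(max(hi, point)),
        n_boot=n_boot, n_pos=len(pos), n_neg=len(neg), scores=scores,
    )


class BlockDiscriminationModel:
    """Logistic classifier for block type from double-delta biomarkers.

    Parameters
    ----------
    data : DataFrame of labelled observations (one row per subject x
        timepoint double delta).
    features : feature columns, e.g. ["ddTr40c"] or all ten ddTrXc columns.
    label_col : binary column; 1 = multichannel block (group II).
    """

    def __init__(self, data: pd.DataFrame, features, label_col: str = "label") -> None:
        features = list(features)
        if not features:
            raise ValueError("at least one feature required")
        sub = data[features + [label_col]].dropna()
        labels = sub[label_col].astype(int)
        if labels.nunique() < 2:
            raise ValueError("both block-type labels must be present")
        self.data = sub
        self.features = features
        self.label_col = label_col

    def fit(self, n_boot: int = 2000, seed: int = 0) -> DiscriminationResult:
        """ML logistic fit; returns the AUC of the in-sample scores.

        Complete separation is reported with a warning but scores are still
        returned (no regularization by default); the AUC is then 1.
        """
        x = sm.add_constant(self.data[self.features].to_numpy(float),
                            has_constant="add")
        y = self.data[self.label_col].to_numpy(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, x).fit(disp=0, maxiter=200, method="bfgs")
                scores = np.asarray(res.predict(x), dtype=float)
            except Exception:
                # fall back to an unpenalized sklearn fit (e.g. separation)
                from sklearn.linear_model import LogisticRegression

                clf = LogisticRegression(penalty=None, max_iter=2000)
                clf.fit(x[:, 1:], y)
                scores = clf.predict_proba(x[:, 1:])[:, 1]
        if roc_auc(scores, y) >= 1.0 - 1e-12:
            warnings.warn("complete separation: logistic scores are degenerate "
                          "(AUC = 1)", stacklevel=2)
        result = bootstrap_auc_ci(scores, y, n_boot=n_boot, seed=seed,
                                  features=self.features)
        result.metadata["in_sample"] = True
        return result


def compare_feature_sets(data: pd.DataFrame, feature_sets: dict[str, list[str]],
                         label_col: str = "label", n_boot: int = 2000,
                         seed: int = 0) -> pd.DataFrame:
    """Fit one logistic model per feature set and tabulate AUCs with CIs."""
    rows = []
    for name, features in feature_sets.items():
        res = BlockDiscriminationModel(data, features, label_col).fit(
            n_boot=n_boot, seed=seed)
        rows.append({"model": name, "auc": res.auc, "ci_lo": res.ci_lo,
                     "ci_hi": res.ci_hi, "n_features": len(features)})
    return pd.DataFrame(rows)
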