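"""Longitudinal change-score analysis with cluster-robust inference.

Both eyes of a patient share unmeasured patient-level factors, so eyes
are not independent observations.  Visit-to-visit changes are therefore
analysed with ordinary least squares point estimates and a cluster-robust
(sandwich) covariance clustered on patient:

    V = c * (X'X)^{-1} [ sum_g X_g' e_g e_g' X_g ] (X'X)^{-1}

with ``c = 1`` (CR0) or the small-sample factor
``c = G/(G-1) * (N-1)/(N-k)`` (CR1, the default), ``G`` clusters, ``N``
observations and ``k`` regressors.  Tests use a t reference distribution
with ``G - 1`` degrees of freedom.

Two model uses cover the study questions: an intercept-only fit on
per-eye changes tests whether the mean change differs from zero, and an
intercept + group-indicator fit tests whether the change differs between
MNV that arises from the choroid (types 1/2) and from the retina
(type 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

VISIT_ORDER = ("pretreatment", "exudation", "post_treatment")
REGIONS = ("circle5", "rim", "circle11")
METRICS = ("thickness_um", "cvi")

Correction = Literal["CR0", "CR1"]


class ClusterRobustOLS:
    """Linear model with cluster-robust variance estimation.

    Parameters
    ----------
    endog
        Response vector, length N.
    exog
        Design matrix (N, k); include the constant column explicitly
        (see :meth:`from_dataframe` which adds one).
    clusters
        Length-N cluster labels (e.g. patient ids).
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        clusters: Sequence,
        exog_names: Sequence[str] | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            self.exog = self.exog.T
        self.clusters = np.asarray(clusters)
        if self.clusters.shape[0] != self.endog.shape[0]:
            raise ValueError("clusters length must match the number of observations")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        y: str,
        x: Sequence[str] = (),
        cluster: str = "patient_id",
    ) -> "ClusterRobustOLS":
        """Build a model from long-format data, prepending an intercept."""
        n = len(data)
        cols = [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in x]
        exog = np.column_stack(cols)
        return cls(
            data[y].to_numpy(dtype=float),
            exog,
            data[cluster].to_numpy(),
            exog_names=["const", *x],
        )

    def fit(self, correction: Correction = "CR1") -> "ClusterRobustOLSResults":
        y, X = self.endog, self.exog
        n, k = X.shape
        if n <= k:
            raise ValueError("need more observations than regressors")
        labels, inverse = np.unique(self.clusters, return_inverse=True)
        g = labels.size
        if g < 2:
            raise ValueError("need at least 2 clusters")
        if np.any(np.bincount(inverse) == n):
            raise ValueError("a single cluster contains all observations")
        xtx = X.T @ X
        if np.linalg.matrix_rank(xtx) < k:
            raise np.linalg.LinAlgError("singular design matrix")
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        # meat: sum over clusters of (X_g' e_g)(X_g' e_g)'
        scores = X * resid[:, None]
        cluster_scores = np.zeros((g, k))
        np.add.at(cluster_scores, inverse, scores)
        meat = cluster_scores.T @ cluster_scores
        if correction == "CR1":
            c = (g / (g - 1)) * ((n - 1) / (n - k))
        elif correction == "CR0":
            c = 1.0
        else:
            raise ValueError(f"unknown correction '{correction}'")
        cov = c * xtx_inv @ meat @ xtx_inv
        return ClusterRobustOLSResults(
            model=self,
            params=beta,
            cov_params=cov,
            resid=resid,
            n_obs=n,
            n_clusters=g,
            correction=correction,
        )


@dataclass
class ClusterRobustOLSResults:
    """Estimates with cluster-robust uncertainty.

    t statistics are referred to a Student t with ``G - 1`` degrees of
    freedom, ``G`` the number of clusters.
    """

    model: ClusterRobustOLS
    params: np.ndarray
    cov_params: np.ndarray
    resid: np.ndarray
    n_obs: int
    n_clusters: int
    correction: str

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def df(self) -> int:
        return self.n_clusters - 1

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        t = self.tvalues
        p = 2 * sps.t.sf(np.abs(t), self.df)
        # degenerate (zero-SE) fits: p = 0 for nonzero effects, 1 at zero
        zero_se = self.bse == 0
        if np.any(zero_se):
            p = np.where(zero_se & (self.params != 0), 0.0, p)
            p = np.where(zero_se & (self.params == 0), 1.0, p)
        return p

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = sps.t.ppf(1 - alpha / 2, self.df)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        lines = [
            "Cluster-robust OLS "
            f"({self.correction}, N={self.n_obs}, clusters={self.n_clusters}, "
            f"df={self.df})",
            f"{'term':>12} {'coef':>12} {'se':>12} {'t':>9} {'p':>9}",
        ]
        ci = self.conf_int()
        for name, b, se, t, p, (lo, hi) in zip(
            self.model.exog_names, self.params, self.bse, self.tvalues, self.pvalues, ci
        ):
            lines.append(
                f"{name:>12} {b:12.4g} {se:12.4g} {t:9.3f} {p:9.4f}"
                f"   [{lo:.4g}, {hi:.4g}]"
            )
        return "\n".join(lines)


def cluster_robust_fit(
    y: np.ndarray,
    design: np.ndarray,
    cluster_ids: Sequence,
    correction: Correction = "CR1",
) -> ClusterRobustOLSResults:
    """Functional wrapper around :class:`ClusterRobustOLS`."""
    return ClusterRobustOLS(y, design, cluster_ids).fit(correction=correction)


# ---------------------------------------------------------------------------
# change scores and study tables


def change_scores(
    records: pd.DataFrame,
    from_visit: str,
    to_visit: str,
    metric: str = "thickness_um",
    region: str = "circle5",
    require_eligible: bool = False,
) -> pd.DataFrame:
    """Per-eye paired changes ``value(to_visit) - value(from_visit)``.

    Eyes missing either visit are dropped (their ids are recorded in the
    result's ``attrs['dropped']``).  With ``require_eligible`` only eyes
    eligible at both visits are kept (used for CVI).
    """
    sub = records[(records["metric"] == metric) & (records["region"] == region)]
    if require_eligible and "eligible" in sub.columns:
        sub = sub[sub["eligible"].astype(bool)]
    pivot = sub.pivot_table(
        index=["patient_id", "eye_id", "mnv_type"],
        columns="visit",
        values="value",
        aggfunc="first",
    )
    dropped = []
    for visit in (from_visit, to_visit):
        if visit not in pivot.columns:
            pivot[visit] = np.nan
    complete = pivot[[from_visit, to_visit]].notna().all(axis=1)
    dropped = [idx[1] for idx in pivot.index[~complete]]
    pivot = pivot[complete]
    out = pivot.reset_index()[["patient_id", "eye_id", "mnv_type"]].copy()
    out["value_from"] = pivot[from_visit].to_numpy()
    out["value_to"] = pivot[to_visit].to_numpy()
    out["change"] = out["value_to"] - out["value_from"]
    out.attrs["dropped"] = dropped
    out.attrs["from_visit"] = from_visit
    out.attrs["to_visit"] = to_visit
    return out


def paired_mean_test(
    changes: pd.DataFrame, correction: Correction = "CR1"
) -> ClusterRobustOLSResults:
    """Mean-change test: intercept-only fit on per-eye changes, clustered
    on patient."""
    model = ClusterRobustOLS(
        changes["change"].to_numpy(),
        np.ones((len(changes), 1)),
        changes["patient_id"].to_numpy(),
        exog_names=["mean_change"],
    )
    return model.fit(correction=correction)


def group_difference_test(
    changes: pd.DataFrame, correction: Correction = "CR1"
) -> ClusterRobustOLSResults:
    """Between-group test: intercept + indicator(type 3) fit on changes.

    The indicator coefficient is the type-3 minus type-1/2 difference in
    mean change.
    """
    ind = (changes["mnv_type"].to_numpy() == 3).astype(float)
    design = np.column_stack([np.ones(len(changes)), ind])
    model = ClusterRobustOLS(
        changes["change"].to_numpy(),
        design,
        changes["patient_id"].to_numpy(),
        exog_names=["type1or2_mean", "type3_difference"],
    )
    return model.fit(correction=correction)


_COMPARISONS = (
    ("pretreatment", "exudation", "Increase", 1.0),
    ("exudation", "post_treatment", "Decrease", -1.0),
    ("pretreatment", "post_treatment", "Change", 1.0),
)


def summarize_tables(
    records: pd.DataFrame, correction: Correction = "CR1"
) -> dict[str, pd.DataFrame]:
    """Build the six study summary tables.

    For each visit comparison an all-eyes table (visit means +- SD,
    change +- SD and cluster-robust p per region and metric) and a
    by-MNV-type table (type 1/2 vs type 3 changes and the
    group-difference p).  A ``Decrease`` row reports the positive
    decrease, ``from - to``.  Groups with fewer than 2 eyes are marked
    insufficient.  CVI rows use eligible eyes only.
    """
    tables: dict[str, pd.DataFrame] = {}
    for i, (v_from, v_to, label, sign) in enumerate(_COMPARISONS, start=1):
        all_rows, type_rows = [], []
        for metric in METRICS:
            for region in REGIONS:
                ch = change_scores(
                    records,
                    v_from,
                    v_to,
                    metric=metric,
                    region=region,
                    require_eligible=(metric == "cvi"),
                )
                if len(ch) < 2:
                    continue
                fit = paired_mean_test(ch, correction=correction)
                all_rows.append(
                    {
                        "metric": metric,
                        "region": region,
                        "n_eyes": len(ch),
                        f"{v_from}_mean": ch["value_from"].mean(),
                        f"{v_from}_sd": ch["value_from"].std(ddof=1),
                        f"{v_to}_mean": ch["value_to"].mean(),
                        f"{v_to}_sd": ch["value_to"].std(ddof=1),
                        f"{label.lower()}_mean": sign * ch["change"].mean(),
                        f"{label.lower()}_sd": ch["change"].std(ddof=1),
                        "p_value": float(fit.pvalues[0]),
                    }
                )
                row: dict = {"metric": metric, "region": region}
                g12 = ch[ch["mnv_type"].isin([1, 2])]
                g3 = ch[ch["mnv_type"] == 3]
                row["n_type1or2"] = len(g12)
                row["n_type3"] = len(g3)
                if len(g12) < 2 or len(g3) < 2:
                    row["insufficient"] = True
                else:
                    row["insufficient"] = False
                    row[f"type1or2_{label.lower()}_mean"] = sign * g12["change"].mean()
                    row[f"type1or2_{label.lower()}_sd"] = g12["change"].std(ddof=1)
                    row[f"type3_{label.lower()}_mean"] = sign * g3["change"].mean()
                    row[f"type3_{label.lower()}_sd"] = g3["change"].std(ddof=1)
                    gfit = group_difference_test(ch, correction=correction)
                    row["p_value"] = float(gfit.pvalues[1])
                type_rows.append(row)
        tables[f"all_eyes_{v_from}_to_{v_to}"] = pd.DataFrame(all_rows)
        tables[f"by_type_{v_from}_to_{v_to}"] = pd.DataFrame(type_rows)
    return tables


def format_table(df: pd.DataFrame, title: str = "") -> str:
    """Aligned plain-text rendering of a summary table."""
    header = f"== {title} ==\n" if title else ""
    if df.empty:
        return header + "(insufficient data)\n"
    return header + df.to_string(index=False, float_format=lambda v: f"{v:.4g}") + "\n"
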