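"""Statistical attribution of MeHg accumulation to microbial/abiotic factors.

The attribution chain works on site-level means with every variable on the
log10 scale and has four stages:

1. **Pearson screen** — candidate factors are retained when their
   product-moment correlation with log10(MeHg) is significant (two-sided t
   test with n-2 df, default alpha 0.05).
2. **Best-subsets selection** — every non-empty subset of the retained
   factors is fitted by ordinary least squares; the subset minimising
   ``AIC = n ln(RSS/n) + 2(k+1)`` is selected (ties toward fewer
   predictors; AICc available).
3. **Relative weights** (Johnson 2000) — the selected model's R^2 is
   decomposed into per-predictor importances through the orthogonal
   approximation of the predictor matrix: with correlation matrix
   ``R_xx = V D^2 V'``, set ``Lambda = R_xx^(1/2)``,
   ``beta = Lambda^-1 r_xy``; the weight of predictor j is
   ``eps_j = sum_k Lambda_jk^2 beta_k^2`` and the weights sum exactly
   to R^2.
4. **Variance partitioning** — adjusted R^2 (Ezekiel) of the microbial set,
   the environmental set, and their union decompose into unique microbial,
   unique environmental, shared, and unexplained fractions; negative
   fractions are reported as-is with a flag.

The module is organised statsmodels-style: :class:`MehgAttribution` is the
model object built from a site table, and ``fit()`` returns a
:class:`MehgAttributionResults` carrying estimates, diagnostics and a
``summary()`` table.  The stage functions are also usable on their own.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------


def pearson_screen(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen candidate factors by Pearson correlation with the response.

    Returns one row per candidate with r, the two-sided p value (t transform,
    n-2 df), and whether it is retained at ``alpha``.  Zero-variance columns
    are skipped with a warning.
    """
    y = data[response].to_numpy(float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations for the screen")
    rows = []
    for name in candidates:
        x = data[name].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("factor %s skipped: zero variance", name)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(dict(factor=name, r=float(r), p=float(p), retained=p < alpha))
    return pd.DataFrame(rows, columns=["factor", "r", "p", "retained"])


def aic_gaussian(n: int, rss: float, k: int) -> float:
    """Profile-Gaussian AIC, counting the error variance as a parameter."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def best_subset_aic(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    criterion: str = "aic",
) -> tuple[list[str], pd.DataFrame]:
    """Exhaustive best-subsets OLS selection under AIC (or AICc).

    Fits every non-empty subset of up to 15 candidates; rank-deficient
    subsets are skipped with a note.  Ties break toward fewer predictors.
    Returns the selected subset and the per-subset score table.
    """
    candidates = list(candidates)
    if len(candidates) > 15:
        raise ValueError("exhaustive enumeration capped at 15 candidates")
    if not candidates:
        raise ValueError("no candidate predictors")
    n = len(data)
    max_k = len(candidates)
    if n <= max_k + 2:
        raise ValueError("too few observations for the largest subset")
    y = data[response].to_numpy(float)
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    best: tuple | None = None
    for k in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            X = np.column_stack(
                [np.ones(n)] + [data[c].to_numpy(float) for c in subset]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                rows.append(dict(subset=subset, k=k, aic=np.nan, note="rank-deficient"))
                continue
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            # an RSS at rounding level is an exact fit: floor it so that all
            # supersets of a perfectly fitting subset tie and the fewer-
            # predictor tie-break decides
            rss = max(rss, 1e-12 * tss)
            score = aic_gaussian(n, rss, k)
            if criterion == "aicc":
                if n - k - 2 <= 0:
                    rows.append(dict(subset=subset, k=k, aic=np.nan, note="aicc undefined"))
                    continue
                score += 2 * (k + 1) * (k + 2) / (n - k - 2)
            elif criterion != "aic":
                raise ValueError("criterion must be 'aic' or 'aicc'")
            rows.append(dict(subset=subset, k=k, aic=score, note=""))
            key = (score, k, subset)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("all candidate subsets were rank-deficient")
    table = pd.DataFrame(rows, columns=["subset", "k", "aic", "note"])
    return list(best[2]), table


def relative_weights(
    data: pd.DataFrame, response: str, predictors: Sequence[str]
) -> pd.DataFrame:
    """Johnson relative weights: decompose R^2 into per-predictor shares.

    Works on the correlation scale, so the weights are invariant to affine
    rescaling of the predictors.  Returns a table with the raw weight (on the
    R^2 scale) and the percentage share; weights sum to R^2 exactly.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("no predictors")
    cols = [response] + predictors
    corr = np.corrcoef(data[cols].to_numpy(float), rowvar=False)
    r_xy = corr[1:, 0]
    r_xx = corr[1:, 1:]
    evals, evecs = np.linalg.eigh(r_xx)
    if evals.min() <= 1e-10:
        raise ValueError("predictor matrix is rank-deficient")
    lam = evecs @ np.diag(np.sqrt(evals)) @ evecs.T  # R_xx^(1/2)
    beta = np.linalg.solve(lam, r_xy)
    weights = (lam**2) @ (beta**2)
    rsq = float(r_xy @ np.linalg.solve(r_xx, r_xy))
    out = pd.DataFrame(
        {
            "factor": predictors,
            "weight": weights,
            "share_pct": 100.0 * weights / rsq if rsq > 0 else np.nan,
        }
    )
    out.attrs["rsquared"] = rsq
    return out


def adjusted_r2(data: pd.DataFrame, response: str, predictors: Sequence[str]) -> float:
    """Ezekiel-adjusted R^2 of an OLS fit."""
    n = len(data)
    p = len(predictors)
    if n <= p + 1:
        raise ValueError("adjusted R^2 undefined: n <= p + 1")
    y = data[response].to_numpy(float)
    X = np.column_stack([np.ones(n)] + [data[c].to_numpy(float) for c in predictors])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(
    data: pd.DataFrame,
    response: str,
    set1: Sequence[str],
    set2: Sequence[str],
) -> dict:
    """Two-set variance partitioning on the adjusted-R^2 scale.

    ``unique1 = adjR2(union) - adjR2(set2)``; ``unique2`` symmetrically;
    ``shared = adjR2(set1) + adjR2(set2) - adjR2(union)``;
    ``unexplained = 1 - adjR2(union)``.  Negative fractions are reported
    as-is and flagged.
    """
    set1, set2 = list(set1), list(set2)
    if not set1 or not set2:
        raise ValueError("both predictor sets must be non-empty")
    union = list(dict.fromkeys(set1 + set2))
    a1 = adjusted_r2(data, response, set1)
    a2 = adjusted_r2(data, response, set2)
    au = adjusted_r2(data, response, union)
    unique1 = au - a2
    unique2 = au - a1
    shared = a1 + a2 - au
    return dict(
        unique1=unique1,
        unique2=unique2,
        shared=shared,
        unexplained=1.0 - au,
        adj_r2_set1=a1,
        adj_r2_set2=a2,
        adj_r2_union=au,
        negative_fraction_flag=min(unique1, unique2, shared) < 0,
    )


def log10_with_offset(series: pd.Series) -> tuple[pd.Series, bool]:
    """log10 transform; zeros are offset by half the smallest positive value.

    Returns the transformed series and a flag marking whether an offset was
    applied.  Negative values are rejected.
    """
    x = series.astype(float)
    if (x < 0).any():
        raise ValueError(f"negative values in {series.name!r} cannot be log-transformed")
    flagged = bool((x == 0).any())
    if flagged:
        positive = x[x > 0]
        if positive.empty:
            raise ValueError(f"column {series.name!r} is all zeros")
        x = x.replace(0.0, positive.min() / 2.0)
    return np.log10(x), flagged


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class MehgAttribution:
    """Site-level attribution model for MeHg accumulation.

    Parameters
    ----------
    data:
        One row per site; response and all candidate predictors already on
        the log10 scale (use :meth:`from_raw` to transform raw
        concentrations/abundances, zeros offset by half the smallest
        positive value).
    microbial, environmental:
        Candidate factor names by set; their union is the candidate pool
        offered to the screen.
    response:
        Column holding log10(MeHg).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        microbial: Sequence[str],
        environmental: Sequence[str],
        response: str = "log10_MeHg",
    ):
        self.data = data.reset_index(drop=True)
        self.microbial = list(microbial)
        self.environmental = list(environmental)
        self.response = response
        if len(self.data) < 3:
            raise ValueError("need at least 3 sites")
        missing = [
            c
            for c in [response, *self.microbial, *self.environmental]
            if c not in self.data.columns
        ]
        if missing:
            raise KeyError(f"columns not in site table: {missing}")
        if self.data[[response, *self.microbial, *self.environmental]].isna().any().any():
            raise ValueError("missing values in fitted columns")

    @classmethod
    def from_raw(
        cls,
        data: pd.DataFrame,
        microbial: Sequence[str],
        environmental: Sequence[str],
        response: str = "MeHg",
    ) -> "MehgAttribution":
        """Build the model from raw-scale columns, log10-transforming all.

        Zero values (e.g. absent lineages) are offset by half the smallest
        positive value in their column; offset columns are flagged in
        ``transform_flags``.
        """
        out = pd.DataFrame(index=data.index)
        flags = {}
        for col in [response, *microbial, *environmental]:
            out[col], flags[col] = log10_with_offset(data[col])
        model = cls(
            out.rename(columns={response: "log10_" + response}),
            microbial,
            environmental,
            response="log10_" + response,
        )
        model.transform_flags = flags
        return model

    def fit(
        self,
        alpha: float = 0.05,
        criterion: str = "aic",
    ) -> "MehgAttributionResults":
        """Run screen -> best-subsets -> relative weights -> partitioning."""
        candidates = self.microbial + self.environmental
        screened = pearson_screen(self.data, self.response, candidates, alpha=alpha)
        retained = list(screened.loc[screened["retained"], "factor"])
        errors: dict[str, str] = {}
        selected: list[str] = []
        subset_table = None
        ols_results = None
        weights = None
        partition = None
        if not retained:
            errors["selection"] = "no factors retained by the Pearson screen"
        else:
            selected, subset_table = best_subset_aic(
                self.data, self.response, retained, criterion=criterion
            )
            X = sm.add_constant(self.data[selected])
            ols_results = sm.OLS(self.data[self.response], X).fit()
            try:
                weights = relative_weights(self.data, self.response, selected)
            except ValueError as exc:
                errors["relative_weights"] = str(exc)
            mic = [f for f in selected if f in self.microbial]
            env = [f for f in selected if f in self.environmental]
            try:
                partition = variance_partition(self.data, self.response, mic, env)
            except ValueError as exc:
                errors["variance_partition"] = str(exc)
        return MehgAttributionResults(
            model=self,
            screened=screened,
            selected=selected,
            subset_table=subset_table,
            ols_results=ols_results,
            relative_weights=weights,
            partition=partition,
            errors=errors,
            alpha=alpha,
            criterion=criterion,
        )


@dataclass
class MehgAttributionResults:
    """Fitted attribution chain: estimates, diagnostics, and a summary."""

    model: MehgAttribution
    screened: pd.DataFrame
    selected: list[str]
    subset_table: pd.DataFrame | None
    ols_results: object | None
    relative_weights: pd.DataFrame | None
    partition: dict | None
    errors: dict[str, str]
    alpha: float
    criterion: str

    @property
    def rsquared(self) -> float | None:
        return None if self.ols_results is None else float(self.ols_results.rsquared)

    @property
    def params(self) -> pd.Series | None:
        return None if self.ols_results is None else self.ols_results.params

    def summary(self) -> str:
        lines = ["MeHg attribution results", "=" * 40]
        lines.append(f"sites: {len(self.model.data)}   alpha: {self.alpha}   "
                     f"criterion: {self.criterion.upper()}")
        lines.append("")
        lines.append("Pearson screen (vs " + self.model.response + "):")
        lines.append(self.screened.to_string(index=False,
                                             float_format=lambda v: f"{v: .4f}"))
        if self.selected:
            lines.append("")
            lines.append(f"selected subset: {', '.join(self.selected)}")
            lines.append(f"model R^2: {self.rsquared:.3f}  "
                         f"(adjusted: {self.ols_results.rsquared_adj:.3f})")
        if self.relative_weights is not None:
            lines.append("")
            lines.append("relative weights (share of explained variance):")
            lines.append(
                self.relative_weights.to_string(
                    index=False, float_format=lambda v: f"{v: .4f}"
                )
            )
        if self.partition is not None:
            lines.append("")
            lines.append("variance partition (adjusted R^2 scale):")
            lines.append(f"  unique microbial:      {self.partition['unique1']: .3f}")
            lines.append(f"  unique environmental:  {self.partition['unique2']: .3f}")
            lines.append(f"  shared:                {self.partition['shared']: .3f}")
            lines.append(f"  unexplained:           {self.partition['unexplained']: .3f}")
            if self.partition["negative_fraction_flag"]:
                lines.append("  (negative fraction present — reported as-is)")
        for stage, message in self.errors.items():
            lines.append(f"[{stage}] {message}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready result bundle."""
        return dict(
            screened=self.screened.to_dict(orient="records"),
            selected=self.selected,
            rsquared=self.rsquared,
            params=None if self.params is None else self.params.to_dict(),
            relative_weights=(
                None
                if self.relative_weights is None
                else self.relative_weights.to_dict(orient="records")
            ),
            partition=self.partition,
            errors=self.errors,
            alpha=self.alpha,
            criterion=self.criterion,
        )


def attribute_mehg(
    data: pd.DataFrame,
    factor_sets: Mapping[str, Sequence[str]],
    response: str = "log10_MeHg",
    alpha: float = 0.05,
    criterion: str = "aic",
) -> MehgAttributionResults:
    """One-shot attribution from a site table and a factor -> set map.

    ``factor_sets`` maps ``"microbial"`` and ``"environmental"`` to factor
    name lists; all columns must already be log10-transformed.
    """
    model = MehgAttribution(
        data,
        microbial=factor_sets.get("microbial", []),
        environmental=factor_sets.get("environmental", []),
        response=response,
    )
    return model.fit(alpha=alpha, criterion=criterion)
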