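"""Group-level inference on investigatory-sniffing metrics.

The central object is :class:`InvestigatorySniffingModel`, a
statsmodels-style model over a tidy per-trial metrics table: a linear
mixed-effects model on the square-root of the percent-time response
(the transform stabilizes variance and improves residual normality for
a bounded, right-skewed percentage), with a treatment fixed effect,
odor as a covariate, and crossed random intercepts for mouse and
dilution.  ``fit()`` returns :class:`SniffingResults`, which carries
the treatment contrast on the model scale alongside the raw-scale group
mean difference in percentage points (the headline effect size), with a
Welch t confidence interval on per-mouse means.

Per-dilution treatment contrasts (one model per dilution, random mouse
intercept) are corrected across the dilution family with the
Benjamini-Hochberg step-up procedure.  Ordinal pathology score tables
are compared by two-sided permutation tests on group means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ContrastResult",
    "InvestigatorySniffingModel",
    "SniffingResults",
    "fit_overall_model",
    "per_dilution_contrasts",
    "bh_adjust",
    "permutation_test",
    "permutation_scores",
]

log = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 20_000


@dataclass(frozen=True)
class ModelSpec:
    """Model structure for the mixed-effects analysis."""

    response: str = "invest_pct"
    transform: str = "sqrt"
    include_odor: bool = True
    include_sex: bool = False
    random_mouse: bool = True
    random_dilution: bool = True

    def __post_init__(self) -> None:
        if self.transform not in ("sqrt", "none"):
            raise ValueError("transform must be 'sqrt' or 'none'")


@dataclass
class ContrastResult:
    """One linear contrast between treatment groups.

    ``estimate``/``se``/``p_raw`` are on the analysis (square-root)
    scale, treated minus control.  ``raw_diff_pct`` is the group mean
    difference of the untransformed response in percentage points,
    control minus treated, so a deficit in the treated group is
    positive.  ``p_bh`` is filled in when the contrast belongs to a
    multiplicity family.
    """

    label: str
    estimate: float
    se: float
    p_raw: float
    p_bh: float | None = None
    raw_diff_pct: float = np.nan
    raw_se: float = np.nan
    raw_ci: tuple[float, float] | None = None
    n_obs: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and not 0 <= self.p_raw <= 1:
            raise ValueError("p_raw outside [0, 1]")


def _welch_diff(a: np.ndarray, b: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Difference of means with Welch SE and 95% t interval."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se = float(np.sqrt(va + vb))
    if se == 0:
        return float(diff), 0.0, (float(diff), float(diff))
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    tcrit = scipy.stats.t.ppf(0.975, df)
    return float(diff), se, (float(diff - tcrit * se), float(diff + tcrit * se))


class InvestigatorySniffingModel:
    """Mixed-effects model of per-trial investigatory sniffing.

    Parameters
    ----------
    table : DataFrame
        Tidy per-trial metrics (one row per trial) with at least
        ``mouse_id``, ``group``, ``odor``, ``log10_dilution`` and the
        response column.  Vehicle rows (``is_vehicle`` True or missing
        dilution) are excluded from modelling.
    spec : ModelSpec
    group_order : (control_label, treated_label), optional
        Defaults to sorted group labels; the first is the reference.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        spec: ModelSpec = ModelSpec(),
        group_order: tuple[str, str] | None = None,
    ) -> None:
        df = table.copy()
        if "is_vehicle" in df.columns:
            df = df[~df["is_vehicle"].astype(bool)]
        df = df[df["log10_dilution"].notna()]
        if df.empty:
            raise ValueError("no odor-trial rows in metrics table")
        groups = sorted(df["group"].unique()) if group_order is None else list(group_order)
        if len(groups) != 2 or not set(groups) <= set(df["group"].unique()):
            raise ValueError(f"need exactly two groups, got {groups}")
        for g in groups:
            if df.loc[df["group"] == g, "mouse_id"].nunique() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 mice")
        resp = df[spec.response].to_numpy(float)
        if spec.transform == "sqrt" and np.any(resp < 0):
            raise ValueError("square-root transform requires a non-negative response")
        self.table = df.reset_index(drop=True)
        self.spec = spec
        self.control, self.treated = groups

    @classmethod
    def from_metrics(cls, table: pd.DataFrame, **kwargs) -> "InvestigatorySniffingModel":
        return cls(table, **kwargs)

    # -- internals ---------------------------------------------------------

    def _prepare(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        y = out[self.spec.response].to_numpy(float)
        out["_y"] = np.sqrt(y) if self.spec.transform == "sqrt" else y
        return out

    def _formula(self, df: pd.DataFrame, with_odor: bool = True) -> str:
        terms = [f"C(group, Treatment('{self.control}'))"]
        if self.spec.include_sex and "sex" in df.columns and df["sex"].nunique() > 1:
            terms.append("C(sex)")
        if with_odor and self.spec.include_odor and df["odor"].nunique() > 1:
            terms.append("C(odor)")
        return "_y ~ " + " + ".join(terms)

    def _fit_mixed(self, df: pd.DataFrame, vc: dict[str, str], label: str):
        """Fit MixedLM with the given variance components, falling back
        to dropping the dilution component on a singular fit."""
        groups = np.ones(len(df))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            for method in ("lbfgs", "powell"):
                try:
                    md = smf.mixedlm(
                        self._formula(df),
                        df,
                        groups=groups,
                        vc_formula=vc,
                        re_formula="0",
                    )
                    res = md.fit(reml=True, method=method, maxiter=300)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res.converged:
                    return res
        if "dilution" in vc:
            log.warning(
                "%s: singular or non-converged fit; dropping dilution "
                "random effect",
                label,
            )
            vc2 = {k: v for k, v in vc.items() if k != "dilution"}
            return self._fit_mixed(df, vc2, label)
        raise RuntimeError(f"mixed model failed to converge for {label}")

    def _treatment_term(self) -> str:
        return f"C(group, Treatment('{self.control}'))[T.{self.treated}]"

    def _raw_difference(self, df: pd.DataFrame):
        per_mouse = df.groupby(["group", "mouse_id"])[self.spec.response].mean()
        c = per_mouse[self.control].to_numpy()
        t = per_mouse[self.treated].to_numpy()
        return _welch_diff(c, t)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "SniffingResults":
        """Fit the overall treatment model and return results."""
        df = self._prepare(self.table)
        raw_diff, raw_se, raw_ci = self._raw_difference(df)
        meta = {
            "transform": self.spec.transform,
            "inference": "large-sample Wald",
            "random_effects": [],
        }
        if df["_y"].nunique() == 1:
            # degenerate (e.g. all-zero response): contrast exactly 0
            contrast = ContrastResult(
                label="overall treatment",
                estimate=0.0,
                se=0.0,
                p_raw=1.0,
                raw_diff_pct=raw_diff,
                raw_se=raw_se,
                raw_ci=raw_ci,
                n_obs=len(df),
                meta=meta | {"degenerate": True},
            )
            return SniffingResults(self, contrast, None)

        vc = {}
        if self.spec.random_mouse:
            vc["mouse"] = "0 + C(mouse_id)"
        if self.spec.random_dilution:
            vc["dilution"] = "0 + C(log10_dilution)"
        res = self._fit_mixed(df, vc, "overall model")
        meta["random_effects"] = sorted(res.model.exog_vc.names)
        term = self._treatment_term()
        contrast = ContrastResult(
            label="overall treatment",
            estimate=float(res.params[term]),
            se=float(res.bse[term]),
            p_raw=float(res.pvalues[term]),
            raw_diff_pct=raw_diff,
            raw_se=raw_se,
            raw_ci=raw_ci,
            n_obs=len(df),
            meta=meta,
        )
        return SniffingResults(self, contrast, res)

    def fit_per_dilution(self) -> list[ContrastResult]:
        """One treatment contrast per dilution, BH-corrected family.

        Each dilution's rows are modelled with the treatment effect,
        odor covariate and a random mouse intercept.  A dilution absent
        from either group yields a missing result and shrinks the BH
        family (logged).
        """
        df = self._prepare(self.table)
        results: list[ContrastResult] = []
        for dil in sorted(df["log10_dilution"].unique()):
            sub = df[df["log10_dilution"] == dil]
            present = set(sub["group"].unique())
            if present != {self.control, self.treated}:
                log.warning(
                    "dilution 1e%g missing from group(s) %s; contrast reported "
                    "missing and BH family reduced",
                    dil,
                    {self.control, self.treated} - present,
                )
                results.append(
                    ContrastResult(
                        label=f"dilution 1e{dil:g}",
                        estimate=np.nan,
                        se=np.nan,
                        p_raw=np.nan,
                        n_obs=len(sub),
                    )
                )
                continue
            raw_diff, raw_se, raw_ci = self._raw_difference(sub)
            if sub["_y"].nunique() == 1:
                est, se, p = 0.0, 0.0, 1.0
            else:
                term = self._treatment_term()
                res = None
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    try:
                        md = smf.mixedlm(
                            self._formula(sub),
                            sub,
                            groups=sub["mouse_id"],
                        )
                        res = md.fit(reml=True, method="lbfgs", maxiter=200)
                    except (np.linalg.LinAlgError, ValueError):
                        res = None
                    if res is None:
                        # near-degenerate response: drop the random
                        # intercept and fall back to OLS
                        log.warning(
                            "dilution 1e%g: mixed fit singular; falling back "
                            "to OLS",
                            dil,
                        )
                        res = smf.ols(self._formula(sub), sub).fit()
                est = float(res.params[term])
                se = float(res.bse[term])
                p = float(res.pvalues[term])
            results.append(
                ContrastResult(
                    label=f"dilution 1e{dil:g}",
                    estimate=est,
                    se=se,
                    p_raw=p,
                    raw_diff_pct=raw_diff,
                    raw_se=raw_se,
                    raw_ci=raw_ci,
                    n_obs=len(sub),
                )
            )
        family = [r for r in results if np.isfinite(r.p_raw)]
        if family:
            adj = bh_adjust([r.p_raw for r in family])
            for r, q in zip(family, adj):
                r.p_bh = float(q)
        return results


class SniffingResults:
    """Fit results for :class:`InvestigatorySniffingModel`.

    Attributes
    ----------
    overall : ContrastResult
        The overall treatment contrast.
    mixed_result : statsmodels MixedLMResults or None
        The underlying fit (None for degenerate responses).
    """

    def __init__(self, model: InvestigatorySniffingModel, overall: ContrastResult, mixed_result):
        self.model = model
        self.overall = overall
        self.mixed_result = mixed_result
        self._per_dilution: list[ContrastResult] | None = None

    def per_dilution(self) -> list[ContrastResult]:
        if self._per_dilution is None:
            self._per_dilution = self.model.fit_per_dilution()
        return self._per_dilution

    def contrasts_frame(self, include_per_dilution: bool = True) -> pd.DataFrame:
        rows = [self.overall] + (self.per_dilution() if include_per_dilution else [])
        return pd.DataFrame(
            {
                "label": [r.label for r in rows],
                "estimate_sqrt": [r.estimate for r in rows],
                "se_sqrt": [r.se for r in rows],
                "p_raw": [r.p_raw for r in rows],
                "p_bh": [r.p_bh for r in rows],
                "raw_diff_pct": [r.raw_diff_pct for r in rows],
                "raw_ci_low": [r.raw_ci[0] if r.raw_ci else np.nan for r in rows],
                "raw_ci_high": [r.raw_ci[1] if r.raw_ci else np.nan for r in rows],
                "n_obs": [r.n_obs for r in rows],
            }
        )

    def summary(self) -> str:
        o = self.overall
        lines = [
            "Investigatory sniffing mixed model",
            "==================================",
            f"response: {self.model.spec.response} "
            f"(transform: {self.model.spec.transform})",
            f"groups: {self.model.control} (reference) vs {self.model.treated}",
            f"random effects: {o.meta.get('random_effects', [])}",
            f"n trials: {o.n_obs}",
            "",
            f"treatment contrast ({self.model.treated} - {self.model.control}, "
            f"sqrt scale): {o.estimate:+.4f} (SE {o.se:.4f}), p = {o.p_raw:.4g}",
            f"raw-scale mean difference ({self.model.control} - "
            f"{self.model.treated}): {o.raw_diff_pct:.2f} percentage points "
            f"(95% CI {o.raw_ci[0]:.2f} to {o.raw_ci[1]:.2f})",
        ]
        return "\n".join(lines)

    def plot_by_dilution(self, ax=None):
        """Group mean +/- SEM of the response across dilutions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.table
        resp = self.model.spec.response
        for g, style in zip((self.model.control, self.model.treated), ("k-o", "0.5")):
            per = df[df["group"] == g].groupby(["log10_dilution", "mouse_id"])[resp].mean()
            mean = per.groupby("log10_dilution").mean()
            sem = per.groupby("log10_dilution").sem()
            ax.errorbar(mean.index, mean, yerr=sem, label=g, fmt="-o")
        ax.set_xlabel("log10 dilution")
        ax.set_ylabel(resp)
        ax.legend()
        return ax


def fit_overall_model(
    table: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    group_order: tuple[str, str] | None = None,
) -> ContrastResult:
    """Overall treatment contrast for a metrics table (model + raw scale)."""
    return InvestigatorySniffingModel(table, spec, group_order).fit().overall


def per_dilution_contrasts(
    table: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    group_order: tuple[str, str] | None = None,
) -> list[ContrastResult]:
    """Per-dilution treatment contrasts with BH-adjusted p values."""
    return InvestigatorySniffingModel(table, spec, group_order).fit_per_dilution()


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_test(
    scores_a,
    scores_b,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided permutation p value for a difference of group means.

    All label assignments are enumerated when their number is at most
    20,000; otherwise ``n_perm`` Monte-Carlo draws are used with +1
    smoothing (``seed`` then controls the draws).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    obs = abs(a.mean() - b.mean())
    total = comb(n, na)
    tol = 1e-12 * (1.0 + obs)
    if total <= EXHAUSTIVE_LIMIT:
        count = 0
        mean_all = pooled.mean()
        for idx in combinations(range(n), na):
            ma = pooled[list(idx)].mean()
            mb = (mean_all * n - ma * na) / (n - na)
            if abs(ma - mb) >= obs - tol:
                count += 1
        return count / total
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 in Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= obs - tol:
            count += 1
    return (1 + count) / (n_perm + 1)


def permutation_scores(
    score_table: pd.DataFrame,
    group_order: tuple[str, str] | None = None,
    score_col: str = "score",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-region permutation tests on mean pathology scores, with BH.

    ``score_table`` holds one row per animal x region with columns
    ``animal_id``, ``group``, ``region`` and the per-animal mean score
    (0-5 scale).  Returns one row per region with raw and BH-adjusted
    two-sided p values.
    """
    df = score_table.copy()
    s = df[score_col].to_numpy(float)
    if np.any((s < 0) | (s > 5)):
        raise ValueError("pathology scores must lie in [0, 5]")
    groups = sorted(df["group"].unique()) if group_order is None else list(group_order)
    if len(groups) != 2:
        raise ValueError("score table must contain exactly two groups")
    rows = []
    for region, sub in df.groupby("region", sort=True):
        a = sub.loc[sub["group"] == groups[0], score_col].to_numpy()
        b = sub.loc[sub["group"] == groups[1], score_col].to_numpy()
        p = permutation_test(a, b, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "region": region,
                "mean_" + groups[0]: a.mean(),
                "mean_" + groups[1]: b.mean(),
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p_raw"].to_numpy())
    return out
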