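"""Mixed-model analysis of the two-period crossover trial.

Each endpoint is analysed with participant as a random component and device
and visit as fixed effects:

* continuous endpoints (residual urine at the first flow-stop, post-void
  residual, peak suction pressure): linear mixed model fitted by REML, with
  residual-df t intervals on the device contrast;
* flow-stop counts: Poisson log-link random-intercept GLMM (adaptive
  Gauss-Hermite quadrature), device effect reported as a rate ratio;
* haematuria: logit-link random-intercept GLMM, device effect reported as
  an odds ratio, optionally adjusted for medical history.

Effect orientation follows the trial's reporting convention: differences
are CEC minus MHZC (positive favours the micro-hole catheter) and ratios
are MHZC over CEC (below 1 favours the micro-hole catheter).

The two co-primary endpoints are combined by fixed-sequence gatekeeping:
the residual-volume hypothesis must reject at alpha before the flow-stop
hypothesis is tested, which controls the family-wise error rate at alpha
without any multiplicity adjustment.  A Wilcoxon signed-rank test on the
within-subject differences backs the normality assumption of the linear
model; its null distribution is enumerated exactly (tie-aware) for up to 25
pairs and approximated normally with a continuity correction above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .glmm import RandomInterceptGLMM

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ModelFit:
    """Estimates, intervals and p-value for one endpoint's analysis."""

    endpoint: str
    family: str                 # gaussian | poisson | binomial
    effect_type: str            # difference | rate_ratio | odds_ratio
    effect: float               # CEC-MHZC difference, or MHZC/CEC ratio
    effect_ci: tuple[float, float]
    p_value: float
    mean_mhzc: float
    mean_mhzc_ci: tuple[float, float]
    mean_cec: float
    mean_cec_ci: tuple[float, float]
    n_obs: int
    n_subjects: int
    converged: bool = True
    covariates: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.effect_ci
        if not (lo <= self.effect <= hi):
            raise DataError("effect estimate outside its confidence interval")
        if not (0.0 <= self.p_value <= 1.0):
            raise DataError("p-value outside [0, 1]")
        if self.effect_type in ("rate_ratio", "odds_ratio") and self.effect <= 0:
            raise DataError("ratios must be positive")


@dataclass(frozen=True)
class GatekeepingResult:
    """Outcome of fixed-sequence testing of ordered endpoints."""

    endpoints: tuple[str, ...]
    decisions: tuple[str, ...]  # rejected | retained | not tested
    alpha: float
    overall_pass: bool


def _prepare(data: pd.DataFrame, endpoint: str, covariates: tuple[str, ...] = ()):
    required = {"subject", "device", "visit", endpoint, *covariates}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"dataset missing columns {sorted(missing)}")
    df = data.dropna(subset=[endpoint]).copy()
    if df.empty:
        raise DataError(f"endpoint {endpoint!r} has no non-missing data")
    both = df.groupby("subject")["device"].nunique()
    if (both == 2).sum() < 2:
        raise DataError("need at least 2 subjects observed under both devices")
    return df


def _design(df: pd.DataFrame, covariates: tuple[str, ...] = ()):
    """Fixed-effects design: intercept (CEC, visit 1), device=MHZC, visit=2."""
    cols = [
        np.ones(len(df)),
        (df["device"] == "MHZC").to_numpy(float),
        (df["visit"] == 2).to_numpy(float),
    ]
    names = ["intercept", "device[MHZC]", "visit[2]"]
    for cov in covariates:
        if cov == "medical_history":
            cols.append((df[cov] == "neurogenic").to_numpy(float))
            names.append("medical_history[neurogenic]")
        else:
            cols.append(df[cov].to_numpy(float))
            names.append(cov)
    return np.column_stack(cols), names


def _device_mean_contrasts(n_params: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear combinations giving device-level means averaged over visits."""
    c_mhzc = np.zeros(n_params)
    c_cec = np.zeros(n_params)
    c_mhzc[0] = c_cec[0] = 1.0
    c_mhzc[1] = 1.0
    c_mhzc[2] = c_cec[2] = 0.5
    return c_mhzc, c_cec


def fit_lmm(
    data: pd.DataFrame,
    endpoint: str,
    covariates: tuple[str, ...] = (),
    alpha: float = ALPHA_DEFAULT,
    force_zero_variance: bool = False,
) -> ModelFit:
    """REML linear mixed model y ~ device + visit + (1 | subject).

    Inference on the device contrast uses a t reference with residual
    degrees of freedom n_obs - n_subjects - (n_fixed - 1), the classical
    within-subject df for a crossover.  ``force_zero_variance`` drops the
    random intercept (OLS), used for degenerate-limit checks.
    """
    import statsmodels.api as sm

    df = _prepare(data, endpoint, covariates)
    y = df[endpoint].to_numpy(float)
    X, names = _design(df, covariates)
    groups = df["subject"].to_numpy()
    notes: list[str] = []
    converged = True

    if force_zero_variance:
        res = sm.OLS(y, X).fit()
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        df_resid = res.df_resid
        notes.append("random-intercept variance forced to zero (OLS)")
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            mod = sm.MixedLM(y, X, groups=groups)
            res = mod.fit(reml=True)
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]
        n_subjects = len(np.unique(groups))
        df_resid = max(len(y) - n_subjects - (X.shape[1] - 1), 1)
        var_re = float(np.squeeze(res.cov_re))
        if var_re < 1e-8:
            notes.append("between-subject variance at the zero boundary")
        if any("converge" in str(w.message).lower() for w in caught):
            converged = False
            notes.append("optimizer reported non-convergence")

    tcrit = stats.t.ppf(1 - alpha / 2, df_resid)
    # device coefficient is MHZC - CEC; report the CEC - MHZC difference
    est = -params[1]
    se = float(np.sqrt(cov[1, 1]))
    tval = est / se if se > 0 else np.inf * np.sign(est)
    p = 2 * stats.t.sf(abs(tval), df_resid) if se > 0 else 0.0

    c_mhzc, c_cec = _device_mean_contrasts(X.shape[1])
    means = {}
    for label, c in (("MHZC", c_mhzc), ("CEC", c_cec)):
        m = float(c @ params)
        s = float(np.sqrt(c @ cov @ c))
        means[label] = (m, (m - tcrit * s, m + tcrit * s))

    return ModelFit(
        endpoint=endpoint,
        family="gaussian",
        effect_type="difference",
        effect=float(est),
        effect_ci=(float(est - tcrit * se), float(est + tcrit * se)),
        p_value=float(p),
        mean_mhzc=means["MHZC"][0],
        mean_mhzc_ci=means["MHZC"][1],
        mean_cec=means["CEC"][0],
        mean_cec_ci=means["CEC"][1],
        n_obs=len(y),
        n_subjects=len(np.unique(groups)),
        converged=converged,
        covariates=covariates,
        notes=tuple(notes),
    )


def _fit_glmm(
    data: pd.DataFrame,
    endpoint: str,
    family: str,
    effect_type: str,
    covariates: tuple[str, ...],
    alpha: float,
    fixed_sigma: float | None,
    n_quad: int,
) -> ModelFit:
    df = _prepare(data, endpoint, covariates)
    y = df[endpoint].to_numpy(float)
    X, names = _design(df, covariates)
    groups = df["subject"].to_numpy()
    notes: list[str] = []

    model = RandomInterceptGLMM(y, X, groups, family=family, n_quad=n_quad)
    res = model.fit(fixed_sigma=fixed_sigma)
    if not res.converged:
        notes.append("optimizer reported non-convergence")
    bse = res.bse()

    degenerate = (
        not np.isfinite(bse[1])
        or bse[1] > 20.0
        or abs(res.params[1]) > 15.0
    )
    if degenerate and family == "binomial":
        # separation fallback: weak ridge on the non-intercept coefficients
        res = model.fit(fixed_sigma=fixed_sigma, penalty=1e-2)
        bse = res.bse()
        notes.append("separation suspected; ridge-penalised fallback fit")
    ci_from_profile = False
    if degenerate and family == "poisson":
        notes.append("degenerate arm; profile-likelihood CI")
        ci_from_profile = True

    zcrit = stats.norm.ppf(1 - alpha / 2)
    coef = float(res.params[1])
    se = float(bse[1])
    if ci_from_profile:
        lo, hi = model.profile_ci(1, level=1 - alpha, fit=res)
    else:
        lo, hi = coef - zcrit * se, coef + zcrit * se
    if se > 0 and np.isfinite(se):
        p = float(2 * stats.norm.sf(abs(coef / se)))
    else:
        p = float("nan")

    c_mhzc, c_cec = _device_mean_contrasts(X.shape[1])
    inv = np.exp if family == "poisson" else (lambda e: 1.0 / (1.0 + np.exp(-e)))
    means = {}
    for label, c in (("MHZC", c_mhzc), ("CEC", c_cec)):
        eta = float(c @ res.params)
        s = float(np.sqrt(max(c @ res.cov_params @ c, 0.0)))
        with np.errstate(over="ignore"):  # degenerate arms give infinite bounds
            means[label] = (
                float(inv(eta)),
                (float(inv(eta - zcrit * s)), float(inv(eta + zcrit * s))),
            )

    return ModelFit(
        endpoint=endpoint,
        family=family,
        effect_type=effect_type,
        effect=float(np.exp(coef)),
        effect_ci=(float(np.exp(lo)), float(np.exp(hi))),
        p_value=min(max(p, 0.0), 1.0) if np.isfinite(p) else 1.0,
        mean_mhzc=means["MHZC"][0],
        mean_mhzc_ci=means["MHZC"][1],
        mean_cec=means["CEC"][0],
        mean_cec_ci=means["CEC"][1],
        n_obs=res.n_obs,
        n_subjects=res.n_groups,
        converged=res.converged,
        covariates=covariates,
        notes=tuple(notes),
    )


def fit_count_glmm(
    data: pd.DataFrame,
    endpoint: str = "n_flow_stops",
    covariates: tuple[str, ...] = (),
    alpha: float = ALPHA_DEFAULT,
    fixed_sigma: float | None = None,
    n_quad: int = 15,
) -> ModelFit:
    """Poisson random-intercept GLMM; device effect as a rate ratio."""
    return _fit_glmm(
        data, endpoint, "poisson", "rate_ratio", covariates, alpha, fixed_sigma, n_quad
    )


def fit_binary_glmm(
    data: pd.DataFrame,
    endpoint: str = "haematuria",
    covariates: tuple[str, ...] = (),
    alpha: float = ALPHA_DEFAULT,
    fixed_sigma: float | None = None,
    n_quad: int = 15,
) -> ModelFit:
    """Logit random-intercept GLMM; device effect as an odds ratio.

    Pass ``covariates=("medical_history",)`` to adjust for neurogenic versus
    non-neurogenic history, as in the post hoc haematuria analysis.
    """
    df = data.copy()
    df[endpoint] = df[endpoint].astype(float)
    return _fit_glmm(
        df, endpoint, "binomial", "odds_ratio", covariates, alpha, fixed_sigma, n_quad
    )


def gatekeep(fits: list[ModelFit], alpha: float = ALPHA_DEFAULT) -> GatekeepingResult:
    """Fixed-sequence testing: each endpoint tested at full alpha only if
    every earlier endpoint rejected."""
    if not fits:
        raise DataError("gatekeeping needs at least one fitted endpoint")
    decisions: list[str] = []
    failed = False
    for fit in fits:
        if failed:
            decisions.append("not tested")
        elif fit.p_value < alpha:
            decisions.append("rejected")
        else:
            decisions.append("retained")
            failed = True
    return GatekeepingResult(
        endpoints=tuple(f.endpoint for f in fits),
        decisions=tuple(decisions),
        alpha=alpha,
        overall_pass=all(d == "rejected" for d in decisions),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+, sum of ranks of positive differences
    p_value: float
    n_used: int       # pairs after dropping zero differences
    method: str       # exact | normal-approx | degenerate
    note: str = ""


def _exact_signed_rank_p(w2: int, ranks2: np.ndarray, alternative: str) -> float:
    """Exact tail probabilities of W+ by dynamic programming.

    Ranks are doubled so tied (half-integer) average ranks become integers;
    the distribution of the doubled statistic is built by convolution over
    the 2^n equally likely sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    differences, alternative: str = "two-sided"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on within-subject differences.

    Zero differences are dropped; tied absolute differences receive average
    ranks.  The null distribution is enumerated exactly for up to 25
    non-zero pairs (tie-aware) and approximated normally with a continuity
    correction and tie-corrected variance beyond that.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise DataError(f"unknown alternative {alternative!r}")
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise DataError("need at least one difference")
    nz = d[d != 0.0]
    n = nz.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", "all differences zero")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    if n <= 25:
        ranks2 = np.rint(2 * ranks)
        w2 = int(round(2 * w_plus))
        p = _exact_signed_rank_p(w2, ranks2, alternative)
        return WilcoxonResult(w_plus, p, n, "exact")

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mu - 0.5) / sd
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mu + 0.5) / sd
        p = float(stats.norm.cdf(z))
    else:
        z = (abs(w_plus - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return WilcoxonResult(w_plus, p, n, "normal-approx")


def within_subject_differences(data: pd.DataFrame, endpoint: str) -> np.ndarray:
    """CEC-minus-MHZC difference per subject with both visits observed."""
    df = _prepare(data, endpoint)
    wide = df.pivot_table(index="subject", columns="device", values=endpoint)
    wide = wide.dropna(subset=["MHZC", "CEC"])
    return (wide["CEC"] - wide["MHZC"]).to_numpy(float)


# ---------------------------------------------------------------------------
# reporting


def percent_reduction(ratio: float) -> float:
    """Percent reduction implied by a ratio below 1: 100 x (1 - ratio)."""
    return 100.0 * (1.0 - ratio)


def summarize_trial(
    fits: list[ModelFit], gatekeeping: GatekeepingResult | None = None
) -> "TrialSummary":
    """Assemble the performance-outcome table plus derived headline lines."""
    if not fits:
        raise DataError("summarize_trial needs at least one fit")
    rows = []
    headlines = []
    for f in fits:
        is_ratio = f.effect_type in ("rate_ratio", "odds_ratio")
        rows.append(
            {
                "endpoint": f.endpoint,
                "mean_mhzc": f.mean_mhzc,
                "mean_mhzc_ci_low": f.mean_mhzc_ci[0],
                "mean_mhzc_ci_high": f.mean_mhzc_ci[1],
                "mean_cec": f.mean_cec,
                "mean_cec_ci_low": f.mean_cec_ci[0],
                "mean_cec_ci_high": f.mean_cec_ci[1],
                "effect_type": f.effect_type,
                "effect": f.effect,
                "effect_ci_low": f.effect_ci[0],
                "effect_ci_high": f.effect_ci[1],
                "p_value": f.p_value,
            }
        )
        if is_ratio:
            headlines.append(
                f"{f.endpoint}: {percent_reduction(f.effect):.0f}% less likely "
                f"with the MHZC ({f.effect_type.replace('_', ' ')} {f.effect:.2f})"
            )
        else:
            headlines.append(
                f"{f.endpoint}: mean difference {f.effect:.2f} "
                f"(CEC {f.mean_cec:.2f} vs MHZC {f.mean_mhzc:.2f})"
            )
    return TrialSummary(pd.DataFrame(rows), tuple(headlines), gatekeeping)


@dataclass(frozen=True)
class TrialSummary:
    table: pd.DataFrame
    headlines: tuple[str, ...]
    gatekeeping: GatekeepingResult | None = None

    def to_markdown(self) -> str:
        cols = [
            ("endpoint", "{}"),
            ("mean_mhzc", "{:.2f}"),
            ("mean_cec", "{:.2f}"),
            ("effect_type", "{}"),
            ("effect", "{:.2f}"),
            ("effect_ci_low", "{:.2f}"),
            ("effect_ci_high", "{:.2f}"),
            ("p_value", "{:.3g}"),
        ]
        header = "| " + " | ".join(name for name, _ in cols) + " |"
        sep = "|" + "|".join(["---"] * len(cols)) + "|"
        lines = [header, sep]
        for _, row in self.table.iterrows():
            lines.append(
                "| " + " | ".join(fmt.format(row[name]) for name, fmt in cols) + " |"
            )
        out = lines
        if self.gatekeeping is not None:
            out.append("")
            out.append(
                "Gatekeeping ("
                + ", ".join(
                    f"{e}: {d}"
                    for e, d in zip(self.gatekeeping.endpoints, self.gatekeeping.decisions)
                )
                + f") — overall pass: {self.gatekeeping.overall_pass}"
            )
        out.append("")
        out.extend(f"- {h}" for h in self.headlines)
        return "\n".join(out)
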