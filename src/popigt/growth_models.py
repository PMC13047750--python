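"""Multilevel growth models of task-metric trajectories across age.

Each performance metric (net/good/bad proportion play; probit reward and
punishment learning rates; frequency sensitivity; go bias) is modelled over
age with subject-level random intercepts and age slopes, in the standard
four-model ladder for accelerated longitudinal designs:

1. unconditional linear growth,
2. unconditional quadratic growth,
3. the winning unconditional model plus a depression-risk group main effect
   and its interaction(s) with age,
4. model 3 plus covariates (nonverbal IQ, sex, administration modality).

Age is centred at 10.98 years (the study design's average baseline age — a
fixed constant, not recomputed from data) so intercepts and group effects
are "baseline effects" at that age.  Estimation is by maximum likelihood
(not REML) so nested likelihood-ratio tests across the ladder are valid.
Singular random-effect fits are simplified in a recorded cascade: drop the
intercept–slope correlation, then the random slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import fit_lmm
from .assoc_stats import bh_fdr

AGE_CENTER = 10.98
TRADITIONAL_METRICS = ("net", "good_prop", "bad_prop")
COMPUTATIONAL_METRICS = ("A_rew_z", "A_pun_z", "beta_f", "beta_b")
ALL_METRICS = TRADITIONAL_METRICS + COMPUTATIONAL_METRICS


def center_age(age) -> np.ndarray | float:
    """Years relative to the 10.98-year average baseline age."""
    return np.asarray(age, dtype=float) - AGE_CENTER if np.ndim(age) else float(age) - AGE_CENTER


@dataclass(frozen=True)
class GrowthSpec:
    polynomial: str = "linear"  # "linear" | "quadratic"
    conditional: bool = False  # risk-group main effect + age interaction(s)
    covariates: tuple[str, ...] = ()  # subset of ("iq", "sex", "onsite")
    moderator: str | None = None  # continuous moderator with age interaction

    def __post_init__(self) -> None:
        if self.polynomial not in ("linear", "quadratic"):
            raise ValueError(f"unknown polynomial {self.polynomial!r}")

    def fixed_terms(self) -> list[str]:
        terms = ["const", "age"]
        if self.polynomial == "quadratic":
            terms.append("age2")
        if self.conditional:
            terms += ["maternal_hx", "age:maternal_hx"]
            if self.polynomial == "quadratic":
                terms.append("age2:maternal_hx")
        terms += list(self.covariates)
        if self.moderator:
            terms += [self.moderator, f"age:{self.moderator}"]
        return terms


@dataclass
class GrowthFit:
    spec: GrowthSpec
    fixed: pd.DataFrame  # coef, se, t, p, ci_lo, ci_hi (index: term)
    sigma2: float
    tau00: float
    tau11: float
    tau01: float
    llf: float
    n_obs: int
    n_subjects: int
    k_fixed: int
    n_vc: int  # number of (co)variance parameters incl residual
    pseudo_r2_total: float
    converged: bool
    simplification: str  # "none" | "uncorrelated" | "intercept_only"
    structure: str = "full"
    dpar: np.ndarray | None = None  # covariance parameters, for warm starts

    @property
    def n_params(self) -> int:
        return self.k_fixed + self.n_vc

    @property
    def icc(self) -> float:
        denom = self.tau00 + self.sigma2
        return self.tau00 / denom if denom > 0 else np.nan


def _design(data: pd.DataFrame, spec: GrowthSpec) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["age"] = data["age_c"].to_numpy(dtype=float)
    for term in spec.fixed_terms():
        if term in ("const", "age"):
            continue
        if term == "age2":
            X["age2"] = X["age"] ** 2
        elif term == "age:maternal_hx":
            X[term] = X["age"] * data["maternal_hx"].to_numpy(dtype=float)
        elif term == "age2:maternal_hx":
            X[term] = X["age"] ** 2 * data["maternal_hx"].to_numpy(dtype=float)
        elif term.startswith("age:"):
            X[term] = X["age"] * data[term.split(":", 1)[1]].to_numpy(dtype=float)
        else:
            X[term] = data[term].to_numpy(dtype=float)
    # constant covariates (e.g. every session on-site) are collinear with
    # the intercept and carry no estimable effect
    drop = [c for c in X.columns
            if c != "const" and float(np.ptp(X[c].to_numpy())) == 0.0]
    return X.drop(columns=drop)


def _singular(res) -> bool:
    """Degenerate random structure: vanishing variance or |corr| ~ 1."""
    if not res.converged:
        return True
    psi = res.psi
    if psi.shape[0] == 1:
        return False
    if psi[0, 0] < 1e-10 or psi[1, 1] < 1e-10:
        return True
    rho = psi[0, 1] / np.sqrt(psi[0, 0] * psi[1, 1])
    return bool(abs(rho) > 0.999)


_SIMPLIFICATION = {"full": "none", "diagonal": "uncorrelated",
                   "intercept": "intercept_only"}


def fit_growth(data: pd.DataFrame, spec: GrowthSpec = GrowthSpec(),
               structure: str | None = None,
               warm_from: GrowthFit | None = None) -> GrowthFit:
    """Fit one metric's multilevel growth model.

    ``data`` holds one row per subject-wave with columns ``subject_id``,
    ``age_c``, ``value`` and whatever covariates the spec references.
    Fixed-effect p-values and CIs use a t reference with n_obs - k_fixed
    residual degrees of freedom.  ``structure`` pins the random-effect
    structure (skipping the singularity cascade), so a ladder of nested
    fixed-effect models stays comparable; ``warm_from`` reuses a nested
    fit's covariance parameters as a starting point, keeping the chain of
    log-likelihoods monotone.
    """
    data = data.dropna(subset=["value", "age_c"])
    if data["wave"].nunique() < 2 if "wave" in data else data["age_c"].nunique() < 2:
        raise ValueError("growth model needs observations at >= 2 waves")
    y = data["value"].to_numpy(dtype=float)
    X = _design(data, spec)
    groups = data["subject_id"].to_numpy()
    age = X["age"].to_numpy()
    extra = warm_from.dpar if warm_from is not None else None
    if structure is not None:
        res = fit_lmm(y, X.to_numpy(), age, groups, structure,
                      extra_start=extra)
        simplification = _SIMPLIFICATION[structure]
    else:
        res = fit_lmm(y, X.to_numpy(), age, groups, "full", extra_start=extra)
        simplification = "none"
        if _singular(res):
            res = fit_lmm(y, X.to_numpy(), age, groups, "diagonal",
                          extra_start=extra)
            simplification = "uncorrelated"
            if _singular(res):
                res = fit_lmm(y, X.to_numpy(), age, groups, "intercept",
                              extra_start=extra)
                simplification = "intercept_only"

    k_fe = X.shape[1]
    n_obs = len(y)
    df_resid = n_obs - k_fe
    fe = res.beta
    se = res.bse
    tvals = fe / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tcrit = stats.t.ppf(0.975, df_resid)
    fixed = pd.DataFrame({
        "coef": fe, "se": se, "t": tvals, "p": pvals,
        "ci_lo": fe - tcrit * se, "ci_hi": fe + tcrit * se,
    }, index=list(X.columns))

    cov = res.psi
    sigma2 = float(res.sigma2)
    tau00 = float(cov[0, 0])
    if simplification == "intercept_only":
        tau11 = 0.0
        tau01 = 0.0
        n_vc = 2  # tau00 + sigma2
    elif simplification == "uncorrelated":
        tau11 = float(cov[1, 1])
        tau01 = 0.0
        n_vc = 3
    else:
        tau11 = float(cov[1, 1])
        tau01 = float(cov[0, 1])
        n_vc = 4

    fitted = res.fitted
    r = np.corrcoef(y, fitted)[0, 1] if np.std(fitted) > 0 else np.nan
    return GrowthFit(
        spec=spec, fixed=fixed, sigma2=sigma2, tau00=tau00, tau11=tau11,
        tau01=tau01, llf=float(res.llf), n_obs=n_obs,
        n_subjects=int(pd.unique(groups).size), k_fixed=k_fe, n_vc=n_vc,
        pseudo_r2_total=float(r**2) if np.isfinite(r) else np.nan,
        converged=bool(res.converged), simplification=simplification,
        structure=res.structure, dpar=res.dpar,
    )


def compare_nested(fit_reduced: GrowthFit, fit_full: GrowthFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p).

    A negative observed 2*delta-loglik (boundary / convergence artefact)
    is floored at zero with a warning.
    """
    chi2 = 2.0 * (fit_full.llf - fit_reduced.llf)
    if chi2 < 0:
        warnings.warn("full model has lower log-likelihood than reduced "
                      "(boundary or convergence issue); chi2 floored at 0")
        chi2 = 0.0
    df = fit_full.n_params - fit_reduced.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, p


def compute_icc(tau00: float, sigma2: float) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma2) from an
    unconditional means model's variance components."""
    if tau00 < 0 or sigma2 < 0:
        raise ValueError("variance components must be nonnegative")
    denom = tau00 + sigma2
    if denom == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return tau00 / denom


def fit_means_model(data: pd.DataFrame) -> GrowthFit:
    """Unconditional means model (random intercept only) for ICC."""
    data = data.dropna(subset=["value"])
    y = data["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    res = fit_lmm(y, X, np.zeros(len(y)), data["subject_id"].to_numpy(),
                  "intercept")
    fe, se = res.beta, res.bse
    fixed = pd.DataFrame({"coef": fe, "se": se, "t": fe / se, "p": np.nan,
                          "ci_lo": np.nan, "ci_hi": np.nan}, index=["const"])
    return GrowthFit(
        spec=GrowthSpec(), fixed=fixed, sigma2=float(res.sigma2),
        tau00=float(res.psi[0, 0]), tau11=0.0, tau01=0.0,
        llf=float(res.llf), n_obs=len(y),
        n_subjects=int(data["subject_id"].nunique()), k_fixed=1, n_vc=2,
        pseudo_r2_total=np.nan, converged=bool(res.converged),
        simplification="intercept_only",
    )


@dataclass
class MetricLadder:
    metric: str
    model1: GrowthFit
    model2: GrowthFit
    winner: str  # "linear" | "quadratic"
    quadratic_lrt: tuple[float, int, float]
    model3: GrowthFit
    model4: GrowthFit
    lrt_vs_model1: tuple[float, int, float]
    lrt_vs_model2: tuple[float, int, float]
    icc: float
    age_p: float = np.nan  # model-4 age-effect p (raw)
    age_fdr: float = np.nan  # BH-adjusted within the computational family


def run_trajectory_ladder(
    long_df: pd.DataFrame,
    covariates: tuple[str, ...] = ("iq", "sex", "onsite"),
    alpha: float = 0.05,
) -> dict[str, MetricLadder]:
    """Run the model-1-to-4 ladder for every metric in the long table.

    The quadratic model replaces the linear one only when the LRT favours it
    at ``alpha``.  Age-effect p-values (model 4) for the four computational
    parameters are BH-adjusted as a single family.  Metrics absent from the
    table are skipped and reported absent.
    """
    out: dict[str, MetricLadder] = {}
    for metric in ALL_METRICS:
        sub = long_df[long_df["metric_name"] == metric]
        if sub.empty:
            continue
        # model 1 selects the random structure (singularity cascade); the
        # rest of the ladder shares it so nested LRT df counts fixed effects
        m1 = fit_growth(sub, GrowthSpec("linear"))
        m2 = fit_growth(sub, GrowthSpec("quadratic"),
                        structure=m1.structure, warm_from=m1)
        chi2q, dfq, pq = compare_nested(m1, m2)
        winner = "quadratic" if pq < alpha else "linear"
        base = m2 if winner == "quadratic" else m1
        m3 = fit_growth(sub, GrowthSpec(winner, conditional=True),
                        structure=m1.structure, warm_from=base)
        m4 = fit_growth(sub, GrowthSpec(winner, conditional=True,
                                        covariates=covariates),
                        structure=m1.structure, warm_from=m3)
        means = fit_means_model(sub)
        out[metric] = MetricLadder(
            metric=metric, model1=m1, model2=m2, winner=winner,
            quadratic_lrt=(chi2q, dfq, pq), model3=m3, model4=m4,
            lrt_vs_model1=compare_nested(m1, m4),
            lrt_vs_model2=compare_nested(m2, m4),
            icc=compute_icc(means.tau00, means.sigma2),
            age_p=float(m4.fixed.loc["age", "p"]),
        )
    comp = [m for m in COMPUTATIONAL_METRICS if m in out]
    if comp:
        adj = bh_fdr([out[m].age_p for m in comp])
        for m, a in zip(comp, adj):
            out[m].age_fdr = float(a)
    return out


def ladder_table(ladders: dict[str, MetricLadder]) -> pd.DataFrame:
    """Flatten the ladders into the conventional report layout: one row per
    model-4 fixed effect per metric, plus variance components, ICC,
    pseudo-R2 and the LRT against the winning unconditional model."""
    rows = []
    for metric, lad in ladders.items():
        m4 = lad.model4
        for term, row in m4.fixed.iterrows():
            rows.append({
                "metric": metric, "row_type": "fixed", "term": term,
                "estimate": row["coef"], "se": row["se"], "t": row["t"],
                "p": row["p"], "ci_lo": row["ci_lo"], "ci_hi": row["ci_hi"],
            })
        ref_lrt = lad.lrt_vs_model2 if lad.winner == "quadratic" else lad.lrt_vs_model1
        extras = {
            "sigma2": m4.sigma2, "tau00": m4.tau00, "tau11": m4.tau11,
            "icc": lad.icc, "pseudo_r2_total": m4.pseudo_r2_total,
            "lrt_chi2": ref_lrt[0], "lrt_df": ref_lrt[1], "lrt_p": ref_lrt[2],
            "age_fdr": lad.age_fdr, "winner": lad.winner,
            "simplification": m4.simplification,
        }
        for k, v in extras.items():
            rows.append({"metric": metric, "row_type": "summary", "term": k,
                         "estimate": v})
    return pd.DataFrame(rows)
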