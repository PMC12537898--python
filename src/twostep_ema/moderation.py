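"""Mixed-model moderation analyses of daily drinking by intention and traits.

The central question: does a subject-level trait (the model-based weight
``omega``, the regression-based MB score, or regional model-based neural
signature means) moderate how strongly weekly drinking intentions translate
into daily alcohol intake?

Two model families share one fixed-effect structure:

* a linear mixed model (LMM) on ``log(grams + 1)`` fitted by maximum
  likelihood, and
* a logistic mixed model (GLMM) on the daily drinking indicator
  (grams > 0 vs abstinence), fitted by variational Bayes.

Intention is dummy-coded with 'none' (no specific intention) as reference:
contrast ``less`` (drink less than usual vs none) and ``no_more`` (drink no
more than usual vs none). Fixed effects are the two contrasts, the traits,
and all trait x contrast cross-level interactions. Random structures:
subject intercepts, optionally uncorrelated intention slopes, optionally
their correlations; the structure is chosen by likelihood-ratio tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

from .ema import INTENTIONS

logger = logging.getLogger(__name__)

STRUCTURES = ("intercept", "slopes", "correlated")
# free random-effect parameters per structure (variances, then covariances)
_N_RE_PARAMS = {"intercept": 1, "slopes": 3, "correlated": 6}


@dataclass(frozen=True)
class ModerationSpec:
    """Specification of one moderation model.

    ``traits`` are subject-level moderators; ``omega`` (bounded in [0, 1])
    and an ``mb_score`` enter uncentered, all other traits and covariates
    are z-standardized across subjects. ``covariates`` are additional
    standardized subject-level regressors (e.g. cognitive measures) that
    also interact with intention.
    """

    dependent: str = "log_grams"  # or "drink_indicator"
    traits: tuple[str, ...] = ("omega",)
    covariates: tuple[str, ...] = ()
    random_structure: str = "slopes"

    def __post_init__(self) -> None:
        if self.dependent not in ("log_grams", "drink_indicator"):
            raise ValueError(f"unknown dependent {self.dependent!r}")
        if self.random_structure not in STRUCTURES:
            raise ValueError(f"unknown random structure {self.random_structure!r}")

    @property
    def moderators(self) -> tuple[str, ...]:
        return tuple(self.traits) + tuple(self.covariates)


@dataclass
class ModerationFit:
    """Coefficient table and variance components of one fitted model."""

    coefficients: pd.DataFrame  # term, estimate, se, stat, df, p, ci_low, ci_high
    variance_components: dict
    llf: float
    converged: bool
    dependent: str
    random_structure: str
    ci_method: str
    trait_ranges: dict
    fe_names: list = field(default_factory=list)
    fe_cov: Optional[np.ndarray] = None
    notes: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def build_design(
    daily: pd.DataFrame, traits: pd.DataFrame, spec: ModerationSpec
) -> tuple[pd.DataFrame, list, dict]:
    """Analysis table with dummies, scaled moderators and interactions.

    Returns (table, fixed-effect term names, observed trait ranges on the
    analysis scale). Only valid days enter. Moderators other than ``omega``
    and ``mb_score`` are z-standardized across subjects before being merged
    onto days, matching the use of standardized neural and cognitive
    regressors next to the bounded behavioural weight.
    """
    valid = daily[daily["valid"]].copy()
    if valid["subject"].nunique() < 10:
        warnings.warn("fewer than 10 subjects; moderation estimates unstable",
                      stacklevel=2)
    sub_traits = traits.drop_duplicates("subject").set_index("subject")
    for cat in INTENTIONS:
        if not (valid["intention"] == cat).any():
            raise ValueError(f"intention category {cat!r} absent from the data")

    df = pd.DataFrame(index=valid.index)
    df["subject"] = valid["subject"].to_numpy()
    if spec.dependent == "log_grams":
        df["y"] = np.log1p(valid["grams"].to_numpy(float))
    else:
        df["y"] = (valid["grams"].to_numpy(float) > 0).astype(float)
    df["less"] = (valid["intention"] == "less").astype(float).to_numpy()
    df["no_more"] = (valid["intention"] == "no_more").astype(float).to_numpy()

    terms = ["Intercept", "less", "no_more"]
    ranges = {}
    for name in spec.moderators:
        if name not in sub_traits.columns:
            raise ValueError(f"trait {name!r} missing from traits table")
        vals = sub_traits[name].astype(float)
        if name not in ("omega", "mb_score"):
            vals = pd.Series(_standardize(vals.to_numpy()), index=vals.index)
        df[name] = df["subject"].map(vals).to_numpy()
        ranges[name] = (float(vals.min()), float(vals.max()))
        terms.append(name)
    for name in spec.moderators:
        for dummy in ("less", "no_more"):
            col = f"{name}_x_{dummy}"
            df[col] = df[name] * df[dummy]
            terms.append(col)
    return df.reset_index(drop=True), terms, ranges


def _lmm_model(df: pd.DataFrame, terms: Sequence[str], structure: str) -> MixedLM:
    rhs = " + ".join(t for t in terms if t != "Intercept")
    formula = f"y ~ {rhs}" if rhs else "y ~ 1"
    kwargs = {}
    if structure == "intercept":
        kwargs["re_formula"] = "1"
    elif structure == "slopes":
        kwargs["re_formula"] = "1"
        kwargs["vc_formula"] = {"less": "0 + less", "no_more": "0 + no_more"}
    else:
        kwargs["re_formula"] = "1 + less + no_more"
    return MixedLM.from_formula(formula, groups="subject", data=df, **kwargs)


def _fit_lmm(df, terms, structure):
    model = _lmm_model(df, terms, structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False)
        if not (result.converged and np.isfinite(result.llf)):
            for method in ("powell", "cg"):
                result = model.fit(reml=False, method=method)
                if result.converged and np.isfinite(result.llf):
                    break
    return result


def _coef_table_lmm(result, terms) -> pd.DataFrame:
    k = len(terms)
    est = np.asarray(result.fe_params)[:k]
    se = np.asarray(result.bse_fe)[:k]
    dof = result.nobs - k  # Wald degrees of freedom
    tstat = est / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    crit = stats.t.ppf(0.975, dof)
    return pd.DataFrame(
        dict(term=terms, estimate=est, se=se, stat=tstat, df=dof, p=p,
             ci_low=est - crit * se, ci_high=est + crit * se)
    )


def fit_moderation(
    daily: pd.DataFrame, traits: pd.DataFrame, spec: ModerationSpec
) -> ModerationFit:
    """Fit the moderation LMM on ``log(grams + 1)`` by maximum likelihood.

    Non-convergence triggers a refit with the next simpler random
    structure, flagged in ``notes``. Confidence intervals are Wald (the
    backend does not profile fixed effects); p-values use t statistics with
    Wald degrees of freedom ``n_obs - n_fixed``.
    """
    if spec.dependent != "log_grams":
        raise ValueError("fit_moderation fits the LMM; use fit_glmm_drinking "
                         "for the drinking indicator")
    df, terms, ranges = build_design(daily, traits, spec)
    notes: list[str] = []
    structure = spec.random_structure
    order = STRUCTURES[: STRUCTURES.index(structure) + 1][::-1]
    result = None
    for st in order:
        result = _fit_lmm(df, terms, st)
        if result.converged and np.isfinite(result.llf):
            structure = st
            break
        notes.append(f"random structure '{st}' did not converge; simplified")
    if not result.converged:
        notes.append("no random structure converged; returning last fit flagged")
    notes.append("ci_method=wald: backend does not support profile CIs")

    vc = dict(residual=float(result.scale))
    vc["intercept"] = float(np.asarray(result.cov_re)[0, 0]) if result.cov_re.size else 0.0
    if result.vcomp is not None and len(result.vcomp):
        for name, v in zip(result.model.exog_vc.names, result.vcomp):
            vc[f"slope_{name}"] = float(v)
    if structure == "correlated" and result.cov_re.size > 1:
        vc["cov_re"] = np.asarray(result.cov_re).tolist()

    k = len(terms)
    return ModerationFit(
        coefficients=_coef_table_lmm(result, terms),
        variance_components=vc,
        llf=float(result.llf),
        converged=bool(result.converged),
        dependent="log_grams",
        random_structure=structure,
        ci_method="wald",
        trait_ranges=ranges,
        fe_names=list(terms),
        fe_cov=np.asarray(result.cov_params())[:k, :k],
        notes=notes,
    )


@dataclass
class StructureSelection:
    """Likelihood-ratio comparison of nested random structures."""

    chosen: str
    table: pd.DataFrame  # structure, n_re_params, llf, chisq, df, p
    notes: list = field(default_factory=list)


def select_random_structure(
    daily: pd.DataFrame, traits: pd.DataFrame, spec: ModerationSpec
) -> StructureSelection:
    """Choose the random structure by sequential likelihood-ratio tests.

    Candidates: subject intercept; + uncorrelated intention slopes;
    + intercept-slope correlations. The chosen structure is the most
    complex one that beats its simpler neighbour at p < 0.05. Variance
    parameters sit on the boundary under the null, making the chi-square
    reference conservative; this is logged, not corrected.
    """
    df, terms, _ = build_design(daily, traits, spec)
    notes = ["boundary null: chi-square LRT p-values are conservative"]
    rows, results = [], []
    for st in STRUCTURES:
        try:
            res = _fit_lmm(df, terms, st)
        except Exception as exc:
            notes.append(f"structure '{st}' unidentifiable: {exc}")
            res = None
        results.append(res)
        rows.append(dict(structure=st, n_re_params=_N_RE_PARAMS[st],
                         llf=np.nan if res is None else float(res.llf)))
    table = pd.DataFrame(rows)
    table["chisq"] = np.nan
    table["df"] = np.nan
    table["p"] = np.nan
    chosen = "intercept"
    for i in (1, 2):
        if results[i] is None or results[i - 1] is None:
            continue
        chisq = 2.0 * (table.loc[i, "llf"] - table.loc[i - 1, "llf"])
        dfree = _N_RE_PARAMS[STRUCTURES[i]] - _N_RE_PARAMS[STRUCTURES[i - 1]]
        p = stats.chi2.sf(max(chisq, 0.0), dfree)
        table.loc[i, ["chisq", "df", "p"]] = [chisq, dfree, p]
        if p < 0.05 and chosen == STRUCTURES[i - 1]:
            chosen = STRUCTURES[i]
        if results[i] is not None and not results[i].converged:
            notes.append(f"structure '{STRUCTURES[i]}' convergence warning")
    return StructureSelection(chosen=chosen, table=table, notes=notes)


@dataclass
class ICCResult:
    icc: Optional[float]
    var_between: float
    var_within: float
    defined: bool

    @property
    def within_share(self) -> Optional[float]:
        return None if self.icc is None else 1.0 - self.icc


def icc(daily: pd.DataFrame) -> ICCResult:
    """Intra-class correlation of ``log(grams + 1)`` from the unconditional model.

    ICC = between-subject variance / (between + within); the complement is
    the within-subject share. Undefined (not an error) when the outcome has
    no variance.
    """
    valid = daily[daily["valid"]]
    y = np.log1p(valid["grams"].to_numpy(float))
    if len(y) == 0 or y.std() == 0:
        return ICCResult(icc=None, var_between=0.0, var_within=0.0, defined=False)
    df = pd.DataFrame(dict(y=y, subject=valid["subject"].to_numpy()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM.from_formula("y ~ 1", groups="subject", data=df).fit(reml=False)
    vb = float(np.asarray(res.cov_re)[0, 0])
    vw = float(res.scale)
    total = vb + vw
    if total <= 0:
        return ICCResult(icc=None, var_between=vb, var_within=vw, defined=False)
    return ICCResult(icc=vb / total, var_between=vb, var_within=vw, defined=True)


def marginal_means(
    fit: ModerationFit,
    at: dict,
    categories: Sequence[str] = INTENTIONS,
) -> pd.DataFrame:
    """Model-predicted outcome per intention category at given trait values.

    For the LMM the linear predictor ``m`` on the log scale is
    back-transformed as ``exp(m) - 1`` grams; CI endpoints are transformed
    the same way and the gram-scale SE uses the delta method. For the
    logistic model predictions are probabilities. Requesting trait values
    outside the observed range triggers an extrapolation warning.
    """
    if fit.fe_cov is None:
        raise ValueError("fit carries no fixed-effect covariance")
    for name, val in at.items():
        lo, hi = fit.trait_ranges.get(name, (-np.inf, np.inf))
        if not (lo <= val <= hi):
            warnings.warn(
                f"marginal mean at {name}={val} extrapolates beyond the "
                f"observed range [{lo:.3g}, {hi:.3g}]",
                stacklevel=2,
            )
    est = fit.coefficients.set_index("term")["estimate"]
    rows = []
    for cat in categories:
        x = np.zeros(len(fit.fe_names))
        for j, term in enumerate(fit.fe_names):
            if term == "Intercept":
                x[j] = 1.0
            elif term in ("less", "no_more"):
                x[j] = 1.0 if cat == term else 0.0
            elif "_x_" in term:
                trait, dummy = term.rsplit("_x_", 1)
                x[j] = at.get(trait, 0.0) * (1.0 if cat == dummy else 0.0)
            else:
                x[j] = at.get(term, 0.0)
        m = float(x @ est.to_numpy())
        se = float(np.sqrt(x @ fit.fe_cov @ x))
        lo, hi = m - 1.96 * se, m + 1.96 * se
        if fit.dependent == "log_grams":
            rows.append(dict(category=cat, link_mean=m, link_se=se,
                             mean=np.expm1(m), se=np.exp(m) * se,
                             ci_low=np.expm1(lo), ci_high=np.expm1(hi)))
        else:
            sig = lambda z: 1.0 / (1.0 + np.exp(-z))
            pm = sig(m)
            rows.append(dict(category=cat, link_mean=m, link_se=se,
                             mean=pm, se=pm * (1 - pm) * se,
                             ci_low=sig(lo), ci_high=sig(hi)))
    return pd.DataFrame(rows)


def fit_glmm_drinking(
    daily: pd.DataFrame, traits: pd.DataFrame, spec: ModerationSpec
) -> ModerationFit:
    """Logistic mixed model of drinking (grams > 0) vs abstinence.

    Same fixed effects as the LMM; random subject intercepts plus, for the
    'slopes' and 'correlated' structures, uncorrelated intention slopes
    (the variational backend does not estimate random-effect correlations;
    a note records the simplification). Complete separation is flagged.
    """
    glmm_spec = ModerationSpec(dependent="drink_indicator", traits=spec.traits,
                               covariates=spec.covariates,
                               random_structure=spec.random_structure)
    df, terms, ranges = build_design(daily, traits, glmm_spec)
    notes: list[str] = []
    y = df["y"].to_numpy(float)
    if y.min() == y.max():
        notes.append("complete separation: outcome is constant")
        coef = pd.DataFrame(
            dict(term=terms, estimate=np.nan, se=np.nan, stat=np.nan,
                 df=np.nan, p=np.nan, ci_low=np.nan, ci_high=np.nan)
        )
        coef["odds_ratio"] = np.nan
        return ModerationFit(coefficients=coef, variance_components={},
                             llf=np.nan, converged=False,
                             dependent="drink_indicator",
                             random_structure=spec.random_structure,
                             ci_method="wald", trait_ranges=ranges,
                             fe_names=list(terms), fe_cov=None, notes=notes)

    subjects = pd.unique(df["subject"])
    sub_idx = pd.Categorical(df["subject"], categories=subjects).codes
    n, nsub = len(df), len(subjects)
    exog = np.column_stack(
        [np.ones(n) if t == "Intercept" else df[t].to_numpy(float) for t in terms]
    )

    def block(w):
        return sparse.csr_matrix((w, (np.arange(n), sub_idx)), shape=(n, nsub))

    vc_blocks = [block(np.ones(n))]
    vcp_names = ["re_intercept"]
    if spec.random_structure in ("slopes", "correlated"):
        vc_blocks += [block(df["less"].to_numpy(float)),
                      block(df["no_more"].to_numpy(float))]
        vcp_names += ["re_less", "re_no_more"]
        if spec.random_structure == "correlated":
            notes.append("GLMM backend estimates uncorrelated random effects; "
                         "'correlated' structure simplified to 'slopes'")
    exog_vc = sparse.hstack(vc_blocks).tocsr()
    ident = np.repeat(np.arange(len(vc_blocks)), nsub)

    model = BinomialBayesMixedGLM(y, exog, exog_vc, ident,
                                  fep_names=list(terms), vcp_names=vcp_names)
    converged = True
    # pin the backend's global-RNG initialization for run-to-run determinism
    state = np.random.get_state()
    try:
        np.random.seed(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit_vb()
    except Exception as exc:  # pragma: no cover
        notes.append(f"VB fit failed ({exc}); MAP fallback")
        result = model.fit_map()
        converged = False
    finally:
        np.random.set_state(state)

    est, se = np.asarray(result.fe_mean), np.asarray(result.fe_sd)
    if np.any(np.abs(est) > 15):
        notes.append("possible separation: extreme coefficient magnitude")
        converged = False
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame(
        dict(term=terms, estimate=est, se=se, stat=z, df=np.inf, p=p,
             ci_low=est - 1.96 * se, ci_high=est + 1.96 * se)
    )
    coef["odds_ratio"] = np.exp(est)
    vc = {name: float(v) for name, v in zip(vcp_names, result.vcp_mean)}
    return ModerationFit(
        coefficients=coef, variance_components=vc,
        llf=np.nan,  # VB ELBO is not a likelihood; no llf reported
        converged=converged, dependent="drink_indicator",
        random_structure=spec.random_structure, ci_method="wald",
        trait_ranges=ranges, fe_names=list(terms),
        fe_cov=np.diag(se ** 2), notes=notes,
    )


def summary_text(fit: ModerationFit) -> str:
    """Plain-text model report."""
    dep = ("log(grams + 1)" if fit.dependent == "log_grams"
           else "P(drinking) [logit]")
    lines = [
        f"Mixed model for {dep}; random structure: {fit.random_structure}; "
        f"ML point estimates, {fit.ci_method} CIs",
        f"converged: {fit.converged}" + (
            f"; llf = {fit.llf:.2f}" if np.isfinite(fit.llf) else ""),
        "",
        fit.coefficients.to_string(index=False,
                                   float_format=lambda v: f"{v: .4f}"),
        "",
        "variance components:",
    ]
    for k, v in fit.variance_components.items():
        if not isinstance(v, list):
            lines.append(f"  {k}: {v:.4f}")
    if fit.notes:
        lines += ["", "notes:"] + [f"  - {n}" for n in fit.notes]
    return "\n".join(lines)


def report_json(fit: ModerationFit) -> dict:
    """Machine-readable model report."""
    return dict(
        dependent=fit.dependent,
        random_structure=fit.random_structure,
        ci_method=fit.ci_method,
        converged=fit.converged,
        llf=None if np.isnan(fit.llf) else fit.llf,
        coefficients=fit.coefficients.replace({np.nan: None}).to_dict(orient="records"),
        variance_components={
            k: v for k, v in fit.variance_components.items() if not isinstance(v, list)
        },
        notes=fit.notes,
    )


def plot_partial_effects(fit: ModerationFit, trait: str, path, n_grid: int = 50):
    """Partial-effect plot of one trait per intention category (log scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = fit.trait_ranges[trait]
    grid = np.linspace(lo, hi, n_grid)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cat in INTENTIONS:
        means = [
            marginal_means(fit, {trait: g}, categories=[cat])["link_mean"].iloc[0]
            for g in grid
        ]
        ax.plot(grid, means, label=cat)
    ax.set_xlabel(trait)
    ylabel = "log(grams + 1)" if fit.dependent == "log_grams" else "logit P(drink)"
    ax.set_ylabel(ylabel)
    ax.legend(title="intention", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
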