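"""Model-agnostic quantification of model-based behaviour from stay/switch data.

A logistic mixed-effects regression predicts whether the first-stage choice
is repeated ("stay") from the previous trial's outcome (reward vs
punishment, by the sign of the points) and transition type (common vs
rare), both effect-coded +-0.5, with random subject slopes for all
within-subject terms. The outcome x transition interaction indexes
model-based control; each subject's MB score is the fixed interaction
effect plus that subject's (shrunken) random interaction slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

logger = logging.getLogger(__name__)

FIXED_TERMS = ("intercept", "outcome", "transition", "outcome_x_transition")


def build_stay_table(trials: pd.DataFrame, include_trial_covariate: bool = True) -> pd.DataFrame:
    """Lag-1 stay/switch rows per subject with +-0.5 effect coding.

    One row per trial from the second onward: ``stay`` is 1 when the current
    first-stage choice repeats the previous one; ``outcome`` is +0.5 after
    reward (previous points > 0) and -0.5 after punishment; ``transition``
    is +0.5 after a common and -0.5 after a rare transition. Subjects with
    fewer than two trials are excluded with a log entry.
    """
    rows = []
    for subject, grp in trials.groupby("subject", sort=False):
        grp = grp.sort_values("trial")
        if len(grp) < 2:
            logger.info("subject %r excluded from stay table: <2 trials", subject)
            continue
        a1 = grp["a1"].to_numpy()
        pts = grp["points"].to_numpy()
        trans = grp["transition"].to_numpy()
        for i in range(1, len(grp)):
            rows.append(
                dict(
                    subject=subject,
                    trial=int(grp["trial"].iloc[i]),
                    stay=int(a1[i] == a1[i - 1]),
                    prev_outcome="reward" if pts[i - 1] > 0 else "punishment",
                    prev_transition=trans[i - 1],
                    outcome=0.5 if pts[i - 1] > 0 else -0.5,
                    transition=0.5 if trans[i - 1] == "common" else -0.5,
                    prev_points=float(pts[i - 1]),
                )
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["outcome_x_transition"] = df["outcome"] * df["transition"]
        if include_trial_covariate:
            # standardized trial number, a drift/fatigue nuisance regressor
            tn = df["trial"].to_numpy(float)
            df["trial_z"] = (tn - tn.mean()) / (tn.std() if tn.std() > 0 else 1.0)
    return df


@dataclass
class StayFit:
    """Fitted stay/switch logistic mixed model."""

    fixed: pd.DataFrame  # term, estimate, se, z, p
    mb_scores: pd.DataFrame  # subject, mb_score, se
    vcp: pd.DataFrame  # random-effect log-SD posterior summaries
    converged: bool
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.fixed.set_index("term").loc[term, "estimate"])

    def z(self, term: str) -> float:
        return float(self.fixed.set_index("term").loc[term, "z"])


def fit_stay_glmm(
    rows: pd.DataFrame,
    include_trial_covariate: bool = False,
    include_magnitude_covariate: bool = False,
) -> StayFit:
    """Fit the stay/switch logistic mixed model by variational Bayes.

    Random structure: per-subject intercepts plus uncorrelated random
    slopes for outcome, transition and their interaction. The optional
    trial-number covariate implements a drift correction to the lag-1
    regression; the optional magnitude covariate (standardized previous
    points) absorbs reward-magnitude effects that the binary reward/
    punishment coding discards and that can make model-free agents appear
    model-based in graded-payoff task variants. Per-subject MB scores are
    fixed interaction + posterior mean of the subject's interaction slope.
    """
    subjects = pd.unique(rows["subject"])
    if len(subjects) < 2:
        raise ValueError("stay GLMM needs at least 2 subjects")
    sub_idx = pd.Categorical(rows["subject"], categories=subjects).codes
    n, nsub = len(rows), len(subjects)

    fe_names = list(FIXED_TERMS)
    cols = [np.ones(n), rows["outcome"].to_numpy(float),
            rows["transition"].to_numpy(float),
            rows["outcome_x_transition"].to_numpy(float)]
    if include_trial_covariate:
        if "trial_z" not in rows:
            raise ValueError("rows lack 'trial_z'; build the table with the covariate")
        fe_names.append("trial_z")
        cols.append(rows["trial_z"].to_numpy(float))
    if include_magnitude_covariate:
        pts = rows["prev_points"].to_numpy(float)
        fe_names.append("magnitude")
        cols.append((pts - pts.mean()) / pts.std())
    exog = np.column_stack(cols)

    def block(w: np.ndarray) -> sparse.csr_matrix:
        return sparse.csr_matrix((w, (np.arange(n), sub_idx)), shape=(n, nsub))

    exog_vc = sparse.hstack(
        [block(np.ones(n)), block(exog[:, 1]), block(exog[:, 2]), block(exog[:, 3])]
    ).tocsr()
    ident = np.repeat(np.arange(4), nsub)

    model = BinomialBayesMixedGLM(
        rows["stay"].to_numpy(float), exog, exog_vc, ident,
        fep_names=fe_names,
        vcp_names=["re_intercept", "re_outcome", "re_transition", "re_interaction"],
    )
    converged = True
    # the backend initializes from the global legacy RNG; pin it locally so
    # identical inputs give identical fits, and restore the caller's state
    state = np.random.get_state()
    try:
        np.random.seed(0)
        result = model.fit_vb()
    except Exception as exc:  # pragma: no cover - backend failure path
        logger.warning("VB fit failed (%s); refitting by MAP", exc)
        result = model.fit_map()
        converged = False
    finally:
        np.random.set_state(state)

    fixed = pd.DataFrame(
        dict(term=fe_names, estimate=result.fe_mean, se=result.fe_sd)
    )
    fixed["z"] = fixed["estimate"] / fixed["se"]
    fixed["p"] = 2.0 * stats.norm.sf(np.abs(fixed["z"]))

    vc = result.vc_mean.reshape(4, nsub)
    vc_sd = result.vc_sd.reshape(4, nsub)
    inter_fe = float(fixed.loc[fixed["term"] == "outcome_x_transition", "estimate"].iloc[0])
    mb = pd.DataFrame(
        dict(subject=subjects, mb_score=inter_fe + vc[3], se=vc_sd[3])
    )
    vcp = pd.DataFrame(
        dict(component=["intercept", "outcome", "transition", "interaction"],
             log_sd_mean=result.vcp_mean, log_sd_sd=result.vcp_sd)
    )
    return StayFit(fixed=fixed, mb_scores=mb, vcp=vcp,
                   converged=converged, n_obs=n)


def write_mb_scores(fit: StayFit, path) -> None:
    fit.mb_scores.to_csv(path, index=False)


def summary_text(fit: StayFit) -> str:
    """Plain-text report of the stay/switch model."""
    lines = [
        "Stay/switch logistic mixed model (variational Bayes)",
        f"observations: {fit.n_obs}, subjects: {len(fit.mb_scores)}",
        "",
        fit.fixed.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
        "",
        "random-effect scales (posterior mean of log SD):",
        fit.vcp.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
    ]
    return "\n".join(lines)
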