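"""Synthetic ecological-momentary-assessment (EMA) drinking data.

The generator emulates a year-long smartphone protocol in a cohort of
drinkers: a prospective drinking-intention item every 8 days with three
categories ("none": no particular intention, "no_more": drink no more than
usual, "less": drink less than usual) and a retrospective consumption item
every 2 days reporting grams of ethanol for each of the two preceding days.

Daily grams are generated either by a two-part hurdle process (logistic
drinking indicator, then log-normal amount) or by a linear mixed model on
``log(grams + 1)`` ("loglinear" family), both with subject random effects
and cross-level trait x intention interactions. Subject traits comprise the
model-based weight ``omega`` and three correlated regional model-based
neural signature means (hippocampus, ventral striatum, vmPFC; standardized
units).

:func:`restructure` applies the day-level mapping used for analysis: an
intention rating covers its query day plus the 7 following days; a
consumption report contributes grams to the two days preceding its query
day; days lacking either stream are invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

INTENTIONS = ("none", "no_more", "less")
TRAITS = ("omega", "hippocampus", "vs", "vmpfc")

# Fixed-effect defaults for the two generator families. Interactions apply
# omega uncentered (it is bounded in [0,1]) and the standardized signatures
# as-is, matching the downstream analysis parameterization.
DEFAULT_FIXED_AMOUNT = {
    "intercept": 3.45,
    "less": 0.14,
    "no_more": 0.29,
    "omega": -0.17,
    "omega:less": -1.06,
    "omega:no_more": -0.49,
    "hippocampus": -0.16,
    "hippocampus:less": -0.75,
    "hippocampus:no_more": -0.36,
    "vs": -0.25,
    "vs:less": 0.38,
    "vs:no_more": 0.54,
    "vmpfc": -0.10,
    "vmpfc:less": 0.17,
    "vmpfc:no_more": 0.0,
}

DEFAULT_FIXED_DRINK = {
    "intercept": 0.66,
    "less": 0.08,
    "no_more": 0.44,
    "omega": -0.36,
    "omega:less": -1.17,
    "omega:no_more": -0.58,
    "hippocampus": 0.01,
    "hippocampus:less": -0.84,
    "hippocampus:no_more": -0.53,
    "vs": -0.33,
    "vs:less": 0.50,
    "vs:no_more": 0.63,
    "vmpfc": -0.27,
    "vmpfc:less": 0.24,
    "vmpfc:no_more": -0.09,
}

DEFAULT_FIXED_LOGLINEAR = {
    "intercept": 2.37,
    "less": 0.14,
    "no_more": 0.29,
    "omega": -0.17,
    "omega:less": -1.06,
    "omega:no_more": -0.49,
}


@dataclass(frozen=True)
class EMAGenConfig:
    """Generator configuration; defaults target the study-scale cohort.

    The calibration anchors for the defaults are a cohort of 67 subjects
    observed up to 359 days with about three quarters of days valid, a
    "less" intention on about a quarter of days, a right-skewed zero-
    inflated daily intake around 32 g/day, and an intra-class correlation
    of ``log(grams + 1)`` around 0.16.
    """

    n_subjects: int = 67
    horizon: int = 359
    start_day: int = 1
    rating_interval: int = 8
    report_interval: int = 2
    window: int = 8
    # intention Markov chain over 8-day blocks
    p_stationary: tuple[float, float, float] = (0.45, 0.30, 0.25)
    persistence: float = 0.4
    # traits
    omega_beta: tuple[float, float] = (2.4, 1.4)
    signature_corr: float = 0.5
    # outcome family
    family: str = "hurdle"  # or "loglinear"
    fixed_amount: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_AMOUNT))
    fixed_drink: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_DRINK))
    fixed_loglinear: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_LOGLINEAR))
    # variance components (log-gram / logit scales)
    sd_intercept_amount: float = 0.4
    sd_resid_amount: float = 0.9
    sd_intercept_drink: float = 0.65
    sd_intercept: float = 0.62  # loglinear random intercept
    sd_slope_less: float = 0.45
    sd_slope_no_more: float = 0.45
    sd_resid: float = 1.4  # loglinear residual
    # share of study days rendered invalid by missing assessments
    p_miss: float = 0.24
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_stationary, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"stationary probabilities must sum to 1, got {tuple(p)}")
        if self.family not in ("hurdle", "loglinear"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (0.0 <= self.p_miss < 1.0):
            raise ValueError("p_miss must be in [0, 1)")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must be in [0, 1)")
        for name in ("sd_intercept_amount", "sd_resid_amount", "sd_intercept_drink",
                     "sd_intercept", "sd_slope_less", "sd_slope_no_more", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "EMAGenConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def rating_days(config: EMAGenConfig) -> np.ndarray:
    """Query days of the intention item: every 8 days from the start day."""
    last = config.start_day + config.horizon - 1
    return np.arange(config.start_day, last + 1, config.rating_interval)


def report_days(config: EMAGenConfig) -> np.ndarray:
    """Query days of the consumption item: every 2 days, covering the horizon.

    A query on day ``q`` reports the grams of days ``q - 1`` and ``q - 2``,
    so queries run from ``start + 2`` until both final study days are
    covered (the last query may fall one day past the horizon).
    """
    n_queries = math.ceil(config.horizon / config.report_interval)
    return config.start_day + config.report_interval * np.arange(1, n_queries + 1)


def _simulate_traits(config: EMAGenConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    omega = rng.beta(*config.omega_beta, size=n)
    c = config.signature_corr
    cov = np.full((3, 3), c)
    np.fill_diagonal(cov, 1.0)
    sigs = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    traits = pd.DataFrame(
        dict(subject=np.arange(n), omega=omega,
             hippocampus=sigs[:, 0], vs=sigs[:, 1], vmpfc=sigs[:, 2])
    )
    # true subject-level random effects of the outcome model
    if config.family == "hurdle":
        traits["re_amount"] = rng.normal(0, config.sd_intercept_amount, n)
        traits["re_drink"] = rng.normal(0, config.sd_intercept_drink, n)
    else:
        traits["re_intercept"] = rng.normal(0, config.sd_intercept, n)
    traits["re_less"] = rng.normal(0, config.sd_slope_less, n)
    traits["re_no_more"] = rng.normal(0, config.sd_slope_no_more, n)
    return traits


def _intention_chain(config: EMAGenConfig, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Markov chain over rating blocks: sticky with stationary redraw.

    With probability ``persistence`` the previous block's intention
    carries over, otherwise a fresh draw from the stationary distribution;
    the stationary law is exactly ``p_stationary``.
    """
    p = np.asarray(config.p_stationary)
    states = np.empty(n_blocks, dtype=np.int64)
    states[0] = rng.choice(3, p=p)
    for b in range(1, n_blocks):
        if rng.random() < config.persistence:
            states[b] = states[b - 1]
        else:
            states[b] = rng.choice(3, p=p)
    return states


def _linear_predictor(fixed: dict, trait_row: pd.Series, less: np.ndarray,
                      no_more: np.ndarray) -> np.ndarray:
    """Evaluate a term->coefficient dict for one subject's day vectors."""
    eta = np.full(less.shape, float(fixed.get("intercept", 0.0)))
    for term, coef in fixed.items():
        if term == "intercept" or coef == 0.0:
            continue
        parts = term.split(":")
        val = np.ones_like(eta)
        for part in parts:
            if part == "less":
                val = val * less
            elif part == "no_more":
                val = val * no_more
            elif part in TRAITS:
                val = val * float(trait_row[part])
            else:
                raise ValueError(f"unknown term component {part!r} in {term!r}")
        eta = eta + coef * val
    return eta


def _daily_grams(config: EMAGenConfig, trait_row: pd.Series, intention: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    less = (intention == 2).astype(float)
    no_more = (intention == 1).astype(float)
    re_slopes = trait_row["re_less"] * less + trait_row["re_no_more"] * no_more
    if config.family == "hurdle":
        eta_d = (_linear_predictor(config.fixed_drink, trait_row, less, no_more)
                 + trait_row["re_drink"] + re_slopes)
        drinks = rng.random(len(less)) < 1.0 / (1.0 + np.exp(-eta_d))
        mu = (_linear_predictor(config.fixed_amount, trait_row, less, no_more)
              + trait_row["re_amount"] + re_slopes)
        amount = np.exp(rng.normal(mu, config.sd_resid_amount))
        return np.where(drinks, amount, 0.0)
    # loglinear: the analysis-scale linear mixed model, grams = exp(y) - 1
    y = (_linear_predictor(config.fixed_loglinear, trait_row, less, no_more)
         + trait_row["re_intercept"] + re_slopes
         + rng.normal(0, config.sd_resid, len(less)))
    return np.maximum(np.expm1(y), 0.0)


def simulate_cohort(
    config: EMAGenConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate traits, intention ratings and consumption reports.

    Missingness is MCAR at the whole-rating / whole-report level, with the
    per-stream rates chosen so the joint share of invalid days equals
    ``p_miss``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    traits = _simulate_traits(config, rng)
    r_days = rating_days(config)
    q_days = report_days(config)
    first, last = config.start_day, config.start_day + config.horizon - 1
    p_stream = 1.0 - math.sqrt(1.0 - config.p_miss)

    ratings_rows, reports_rows = [], []
    for _, trait_row in traits.iterrows():
        subject = int(trait_row["subject"])
        chain = _intention_chain(config, len(r_days), rng)
        # per-day true intention from the 8-day blocks
        day_idx = (np.arange(first, last + 1) - first) // config.rating_interval
        intention = chain[day_idx]
        grams = _daily_grams(config, trait_row, intention, rng)

        keep_rating = rng.random(len(r_days)) >= p_stream
        for d, st, keep in zip(r_days, chain, keep_rating):
            if keep:
                ratings_rows.append(
                    dict(subject=subject, query_day=int(d), category=INTENTIONS[st])
                )
        keep_report = rng.random(len(q_days)) >= p_stream
        for q, keep in zip(q_days, keep_report):
            if not keep:
                continue
            g = {}
            for off, col in ((1, "grams_day_minus_1"), (2, "grams_day_minus_2")):
                day = int(q) - off
                g[col] = float(grams[day - first]) if first <= day <= last else np.nan
            reports_rows.append(dict(subject=subject, query_day=int(q), **g))

    ratings = pd.DataFrame(ratings_rows, columns=["subject", "query_day", "category"])
    reports = pd.DataFrame(
        reports_rows,
        columns=["subject", "query_day", "grams_day_minus_1", "grams_day_minus_2"],
    )
    return traits, ratings, reports


def restructure(
    ratings: pd.DataFrame, reports: pd.DataFrame, window: int = 8
) -> pd.DataFrame:
    """Day-level records from raw ratings and reports.

    Each rating covers its query day and the ``window - 1`` following days;
    when windows overlap, the later rating wins. Each report contributes
    grams to the two days preceding its query day. A day is valid only when
    both an intention and a grams value are defined for it. Conflicting
    duplicate grams for one day raise an error listing the conflicts.
    """
    intention_map: dict[tuple, str] = {}
    for row in ratings.sort_values(["subject", "query_day"]).itertuples(index=False):
        for d in range(int(row.query_day), int(row.query_day) + window):
            intention_map[(row.subject, d)] = row.category

    grams_map: dict[tuple, float] = {}
    conflicts = []
    for row in reports.itertuples(index=False):
        for off, val in ((1, row.grams_day_minus_1), (2, row.grams_day_minus_2)):
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            key = (row.subject, int(row.query_day) - off)
            if key in grams_map and grams_map[key] != float(val):
                conflicts.append((key[0], key[1], grams_map[key], float(val)))
            else:
                grams_map[key] = float(val)
    if conflicts:
        listing = "; ".join(
            f"subject {s} day {d}: {a} g vs {b} g" for s, d, a, b in conflicts[:10]
        )
        raise ValueError(
            f"{len(conflicts)} conflicting duplicate grams entries: {listing}"
        )

    keys = sorted(set(intention_map) | set(grams_map))
    rows = []
    for key in keys:
        grams = grams_map.get(key)
        intent = intention_map.get(key)
        rows.append(
            dict(subject=key[0], day=key[1],
                 grams=np.nan if grams is None else grams,
                 intention="" if intent is None else intent,
                 valid=grams is not None and intent is not None)
        )
    return pd.DataFrame(rows, columns=["subject", "day", "grams", "intention", "valid"])


@dataclass
class EMASummary:
    """Cohort-level descriptives of the restructured daily data."""

    n_subjects: int
    valid_days_mean: float
    valid_days_sd: float
    mean_grams: float
    sd_grams: float
    pct_abstinent: float
    pct_intention: dict
    spearman: dict

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(daily: pd.DataFrame, traits: Optional[pd.DataFrame] = None) -> EMASummary:
    """Descriptive report on valid days; optional trait correlations.

    When ``traits`` is given, reports Spearman correlations between each
    trait and the subject's proportion of days with the "less" intention.
    """
    valid = daily[daily["valid"]]
    if len(valid) == 0:
        raise ValueError("no valid days to summarize")
    counts = valid.groupby("subject").size()
    grams = valid["grams"].to_numpy(float)
    pct_int = {
        cat: float((valid["intention"] == cat).mean() * 100.0) for cat in INTENTIONS
    }
    spearman = {}
    if traits is not None:
        share_less = (
            valid.assign(is_less=valid["intention"] == "less")
            .groupby("subject")["is_less"].mean()
        )
        merged = traits.set_index("subject").join(share_less.rename("share_less"), how="inner")
        for trait in TRAITS:
            if trait in merged and merged["share_less"].std() > 0:
                rho, p = stats.spearmanr(merged[trait], merged["share_less"])
                spearman[trait] = dict(rho=float(rho), p=float(p))
    return EMASummary(
        n_subjects=int(valid["subject"].nunique()),
        valid_days_mean=float(counts.mean()),
        valid_days_sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        mean_grams=float(grams.mean()),
        sd_grams=float(grams.std(ddof=1)) if len(grams) > 1 else 0.0,
        pct_abstinent=float((grams == 0).mean() * 100.0),
        pct_intention=pct_int,
        spearman=spearman,
    )
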