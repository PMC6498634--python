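"""Seeded synthetic ED cohort generator.

Emulates a registry cohort of women aged 15–70 who sought at least one
emergency-department visit for aggression, with the statistical structure the
downstream analysis assumes:

* ~0.47 % of women carry a violence diagnosis (WVV) in their ED history;
* diagnoses and traumas fall into the 29 analysis categories;
* four latent *community profiles* plant elevated co-occurrence among small
  sets of categories, each anchored to one specific violence code;
* violence status follows a logistic model on the woman's realized
  category indicators and demographics.

The canonical generative unit is the per-woman *history* — the 29-dimensional
indicator vector over the look-back window — drawn from closed-form presence
probabilities ``1 - (1 - p_c)^v`` given the per-visit occurrence probability
``p_c`` and the visit count ``v``. Visit rows are then materialized to realize
exactly those indicators, so truth labels are unambiguous: the violence flag
is equivalent to violence-code presence by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import nbinom

from .categories import (
    CATEGORIES,
    N_CATEGORIES,
    VIOLENCE_CATEGORIES,
    VIOLENCE_CODES,
    category_id,
)

__all__ = [
    "CommunityProfile",
    "GeneratorConfig",
    "SyntheticCohort",
    "ConfigError",
    "default_config",
    "planted_recovery_config",
    "generate_histories",
    "generate_population",
    "generate_visits",
    "expected_cooccurrence",
    "planted_partition",
    "write_cohort",
]

AGE_GROUPS = ("15-24", "25-34", "35-54", "55-70")
AGE_BOUNDS = {"15-24": (15, 24), "25-34": (25, 34), "35-54": (35, 54), "55-70": (55, 70)}

#: Indicator names entering the risk model (the 12 key diagnoses/traumas).
MODEL_PREDICTORS = (
    "infectious",
    "symptoms_ill_defined",
    "other_diagnoses",
    "psychoses",
    "alcohol_substance_abuse",
    "circulatory",
    "pregnancy_related",
    "genitourinary",
    "respiratory",
    "trauma_road",
    "trauma_other",
    "repeated_aggression",
)

#: Demographic model terms (dummy name -> how it is realized).
DEMOGRAPHIC_TERMS = (
    "age_25_34",
    "age_35_54",
    "age_55_70",
    "residence_metro",
    "nationality_italian",
)

#: Generating log-odds defaults: natural logs of the odds ratios reported for
#: the Lazio cohort predictive model. Config values, not claims.
DEFAULT_TRUE_ORS = {
    "infectious": 0.80,
    "symptoms_ill_defined": 1.06,
    "other_diagnoses": 1.37,
    "psychoses": 2.28,
    "alcohol_substance_abuse": 2.05,
    "circulatory": 1.09,
    "pregnancy_related": 1.42,
    "genitourinary": 1.13,
    "respiratory": 1.11,
    "trauma_road": 0.90,
    "trauma_other": 1.28,
    "repeated_aggression": 2.35,
    "age_25_34": 0.66,
    "age_35_54": 0.45,
    "age_55_70": 0.18,
    "residence_metro": 1.70,
    "nationality_italian": 0.58,
}

#: Per-visit baseline occurrence probability for every emittable category.
#: Ordering of magnitudes echoes the reported visit mix (ill-defined symptoms
#: and traumatic/musculoskeletal most frequent; psychoses and substance abuse
#: rare; unintentional trauma most often in an unspecified "other" place).
DEFAULT_BASELINE_PROBS = {
    "infectious": 0.03,
    "psychoses": 0.01,
    "alcohol_substance_abuse": 0.01,
    "other_mental": 0.03,
    "neurological": 0.04,
    "circulatory": 0.04,
    "genitourinary": 0.06,
    "respiratory": 0.06,
    "digestive": 0.08,
    "symptoms_ill_defined": 0.25,
    "pregnancy_related": 0.05,
    "head_face": 0.15,
    "traumatic_musculoskeletal": 0.25,
    "other_diagnoses": 0.15,
    "missing_diagnosis": 0.08,
    "trauma_work_school": 0.03,
    "trauma_road": 0.08,
    "trauma_home": 0.05,
    "trauma_other": 0.15,
}

#: A representative ICD9-CM code per diagnostic category, used when
#: materializing visit rows. Each maps back to its own category.
REPRESENTATIVE_CODES = {
    "infectious": "034.0",
    "psychoses": "295.30",
    "alcohol_substance_abuse": "303.00",
    "other_mental": "300.00",
    "neurological": "346.90",
    "circulatory": "401.9",
    "genitourinary": "599.0",
    "respiratory": "486",
    "digestive": "535.50",
    "symptoms_ill_defined": "789.00",
    "pregnancy_related": "646.90",
    "head_face": "920",
    "traumatic_musculoskeletal": "845.00",
    "other_diagnoses": "216.0",
}

_CODE_OF_VIOLENCE_CAT = {cat: code for code, cat in VIOLENCE_CODES.items()}

#: Categories realizable directly at a visit (everything except the violence
#: codes, which follow the violence flag, and repeated_aggression, which is
#: derived from the aggression-visit count).
EMITTABLE = tuple(
    c for c in CATEGORIES if c not in VIOLENCE_CATEGORIES and c != "repeated_aggression"
)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class CommunityProfile:
    """A planted co-occurrence community.

    ``elevated`` gives per-visit occurrence probabilities replacing the
    baseline for member categories; ``violence_code`` is the dotted ICD9-CM
    violence code this pattern is anchored to. ``repeat_prob`` optionally
    overrides the per-extra-visit aggression probability (the partner-abuse
    pattern is characterized by repeated aggression).
    """

    name: str
    violence_code: str
    elevated: dict[str, float]
    repeat_prob: float | None = None


def default_profiles() -> list[CommunityProfile]:
    """Four profiles mirroring the violence-related patterns reported for the
    Lazio cohort (psychological abuse, partner abuse, multi-type maltreatment,
    sexual abuse)."""
    return [
        CommunityProfile(
            "psychological_abuse",
            "995.82",
            {"alcohol_substance_abuse": 0.05, "circulatory": 0.20, "infectious": 0.15},
        ),
        CommunityProfile(
            "partner_abuse",
            "V61.11",
            {"psychoses": 0.05, "genitourinary": 0.30, "trauma_road": 0.40},
            repeat_prob=0.30,
        ),
        CommunityProfile(
            "maltreatment",
            "995.84",
            {"respiratory": 0.30, "symptoms_ill_defined": 0.60, "trauma_other": 0.50},
        ),
        CommunityProfile(
            "sexual_abuse",
            "995.83",
            {"pregnancy_related": 0.25},
        ),
    ]


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults emulate the Lazio 2003–2015 aggression cohort: 124,691 women,
    0.47 % WVV prevalence, a mean of ~3.2 ED visits per woman over the 3-year
    look-back, and demographic margins close to the published summary table.
    """

    n_women: int = 124_691
    baseline_prevalence: float = 0.0047
    age_group_probs: tuple[float, float, float, float] = (0.1474, 0.2569, 0.4769, 0.1188)
    foreign_prob: float = 0.309
    metro_prob: float = 0.519
    community_profiles: list[CommunityProfile] = field(default_factory=default_profiles)
    profile_probs: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05)
    baseline_category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PROBS)
    )
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {k: float(np.log(v)) for k, v in DEFAULT_TRUE_ORS.items()}
    )
    visits_mean: float = 3.21
    visits_dispersion: float = 1.0
    aggression_repeat_prob: float = 0.076
    extra_violence_code_prob: float = 0.0
    intercept: float | None = None  # None -> calibrated to baseline_prevalence
    lookback_years: int = 3
    period: tuple[int, int] = (2003, 2015)
    seed: int = 0

    def validate(self) -> None:
        if self.n_women <= 0:
            raise ConfigError("n_women must be positive")
        for name in ("baseline_prevalence", "foreign_prob", "metro_prob",
                     "aggression_repeat_prob", "extra_violence_code_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if len(self.age_group_probs) != 4 or any(p < 0 for p in self.age_group_probs):
            raise ConfigError("age_group_probs must be 4 non-negative values")
        if abs(sum(self.age_group_probs) - 1.0) > 1e-12:
            raise ConfigError("age_group_probs must sum to 1")
        if len(self.community_profiles) != 4:
            raise ConfigError("community_profiles must contain exactly 4 profiles")
        if len(self.profile_probs) != len(self.community_profiles):
            raise ConfigError("profile_probs must match community_profiles in length")
        if any(p < 0 for p in self.profile_probs) or sum(self.profile_probs) > 1.0 + 1e-12:
            raise ConfigError("profile_probs must be non-negative and sum to at most 1")
        for prof in self.community_profiles:
            if prof.violence_code not in VIOLENCE_CODES:
                raise ConfigError(
                    f"community_profiles: {prof.violence_code!r} is not a violence code"
                )
            for cat, p in prof.elevated.items():
                if cat not in EMITTABLE:
                    raise ConfigError(
                        f"community_profiles: {cat!r} is not an emittable category"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"community_profiles: probability for {cat!r} not in [0, 1]")
        for cat, p in self.baseline_category_probs.items():
            if cat not in EMITTABLE:
                raise ConfigError(f"baseline_category_probs: unknown category {cat!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"baseline_category_probs: {cat!r} not in [0, 1]")
        if self.visits_mean < 1.0:
            raise ConfigError("visits_mean must be >= 1 (one aggression visit is mandatory)")
        if self.visits_dispersion <= 0:
            raise ConfigError("visits_dispersion must be positive")
        if self.lookback_years <= 0:
            raise ConfigError("lookback_years must be a positive integer")

    # -- derived quantities -------------------------------------------------

    def per_visit_probs(self, profile_index: int | None) -> np.ndarray:
        """Per-visit occurrence probability for each of the 29 categories
        under the given latent profile (None = background)."""
        p = np.zeros(N_CATEGORIES)
        for cat, v in self.baseline_category_probs.items():
            p[category_id(cat)] = v
        if profile_index is not None:
            for cat, v in self.community_profiles[profile_index].elevated.items():
                p[category_id(cat)] = v
        return p

    def repeat_prob_for(self, profile_index: int | None) -> float:
        if profile_index is not None:
            rp = self.community_profiles[profile_index].repeat_prob
            if rp is not None:
                return rp
        return self.aggression_repeat_prob

    def visit_count_pmf(self, tail: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
        """Support and pmf of the visit count (1 + negative binomial)."""
        mu = self.visits_mean - 1.0
        r = self.visits_dispersion
        if mu <= 0:
            return np.array([1]), np.array([1.0])
        p = r / (r + mu)
        kmax = int(nbinom.ppf(1.0 - tail, r, p)) + 1
        ks = np.arange(0, kmax + 1)
        pmf = nbinom.pmf(ks, r, p)
        pmf = pmf / pmf.sum()
        return ks + 1, pmf


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def planted_recovery_config(n_women: int = 20_000, elevation: float = 10.0,
                            baseline: float = 0.02) -> GeneratorConfig:
    """Strong-signal configuration for planted-community recovery checks.

    Every emittable category shares one small baseline per-visit probability;
    each profile elevates its member categories by ``elevation`` (>= 5x);
    violence prevalence is raised to 5 % and the generating coefficients put
    large weight on profile categories, so each profile's violence code
    attaches firmly to its community in the co-occurrence structure. Every
    woman belongs to one of the four profiles, so the five violence codes
    not anchored to a profile never occur and stay isolated.
    """
    probs = {c: baseline for c in EMITTABLE}
    lift = min(elevation * baseline, 0.75)
    profiles = [
        CommunityProfile("psychological_abuse", "995.82",
                         {c: lift for c in ("alcohol_substance_abuse", "circulatory", "infectious")}),
        CommunityProfile("partner_abuse", "V61.11",
                         {c: lift for c in ("psychoses", "genitourinary", "trauma_road")}),
        CommunityProfile("maltreatment", "995.84",
                         {c: lift for c in ("respiratory", "symptoms_ill_defined", "trauma_other")}),
        CommunityProfile("sexual_abuse", "995.83",
                         {c: lift for c in ("pregnancy_related", "digestive")}),
    ]
    coef = {k: 0.0 for k in list(MODEL_PREDICTORS) + list(DEMOGRAPHIC_TERMS)}
    for prof in profiles:
        for cat in prof.elevated:
            if cat in coef:
                coef[cat] = float(np.log(8.0))
    cfg = GeneratorConfig(
        n_women=n_women,
        baseline_prevalence=0.05,
        community_profiles=profiles,
        profile_probs=(0.25, 0.25, 0.25, 0.25),
        baseline_category_probs=probs,
        true_coefficients=coef,
    )
    cfg.validate()
    return cfg


def planted_partition(config: GeneratorConfig) -> dict[str, str]:
    """Truth partition: category -> profile name, for categories elevated in
    exactly one profile, plus each profile's violence code."""
    counts: dict[str, int] = {}
    for prof in config.community_profiles:
        for cat in prof.elevated:
            counts[cat] = counts.get(cat, 0) + 1
    out: dict[str, str] = {}
    for prof in config.community_profiles:
        out[VIOLENCE_CODES[prof.violence_code]] = prof.name
        for cat in prof.elevated:
            if counts[cat] == 1:
                out[cat] = prof.name
    return out


@dataclass
class SyntheticCohort:
    """Generated cohort: per-woman truth table and (optionally) visit rows."""

    women: pd.DataFrame
    truth: GeneratorConfig
    visits: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# core draws
# ---------------------------------------------------------------------------

def _profile_index_array(config: GeneratorConfig, rng: np.random.Generator,
                         n: int) -> np.ndarray:
    """-1 for no profile, else profile index."""
    probs = np.array([1.0 - sum(config.profile_probs), *config.profile_probs])
    return rng.choice(len(probs), size=n, p=probs) - 1


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator, n: int) -> dict:
    """Draw everything upstream of the violence flag for n women."""
    age_idx = rng.choice(4, size=n, p=np.asarray(config.age_group_probs))
    foreign = rng.random(n) < config.foreign_prob
    metro = rng.random(n) < config.metro_prob
    profile = _profile_index_array(config, rng, n)

    mu = config.visits_mean - 1.0
    r = config.visits_dispersion
    if mu > 0:
        extra = rng.negative_binomial(r, r / (r + mu), size=n)
    else:
        extra = np.zeros(n, dtype=int)
    n_visits = 1 + extra

    repeat_p = np.full(n, config.aggression_repeat_prob)
    for k, prof in enumerate(config.community_profiles):
        if prof.repeat_prob is not None:
            repeat_p[profile == k] = prof.repeat_prob
    n_aggression = 1 + rng.binomial(extra, repeat_p)

    # per-visit probability matrix, then history-level presence
    pmat = np.tile(config.per_visit_probs(None), (n, 1))
    for k in range(len(config.community_profiles)):
        mask = profile == k
        if mask.any():
            pmat[mask] = config.per_visit_probs(k)
    presence_prob = 1.0 - (1.0 - pmat) ** n_visits[:, None]
    emit_ids = [category_id(c) for c in EMITTABLE]
    indicators = np.zeros((n, N_CATEGORIES), dtype=bool)
    u = rng.random((n, len(emit_ids)))
    indicators[:, emit_ids] = u < presence_prob[:, emit_ids]
    indicators[:, category_id("repeated_aggression")] = n_aggression >= 2

    return {
        "age_idx": age_idx,
        "foreign": foreign,
        "metro": metro,
        "profile": profile,
        "n_visits": n_visits,
        "n_aggression": n_aggression,
        "indicators": indicators,
    }


def _linear_predictor(config: GeneratorConfig, cov: dict) -> np.ndarray:
    """Non-intercept part of the generating logit."""
    coef = config.true_coefficients
    ind = cov["indicators"]
    eta = np.zeros(len(ind))
    for name in MODEL_PREDICTORS:
        b = coef.get(name, 0.0)
        if b:
            eta += b * ind[:, category_id(name)]
    age = cov["age_idx"]
    for j, name in enumerate(("age_25_34", "age_35_54", "age_55_70"), start=1):
        b = coef.get(name, 0.0)
        if b:
            eta += b * (age == j)
    b = coef.get("residence_metro", 0.0)
    if b:
        eta += b * cov["metro"]
    b = coef.get("nationality_italian", 0.0)
    if b:
        eta += b * (~cov["foreign"])
    return eta


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


_CALIBRATION_SEED = 202_303  # internal stream: calibration independent of cohort seed
_CALIBRATION_DRAWS = 200_000


def calibrated_intercept(config: GeneratorConfig) -> float:
    """Intercept making the marginal violence prevalence equal
    ``baseline_prevalence``, by root-finding on a fixed-seed Monte-Carlo
    sample of linear predictors."""
    if config.intercept is not None:
        return config.intercept
    if config.baseline_prevalence <= 0.0:
        return -np.inf
    if config.baseline_prevalence >= 1.0:
        return np.inf
    rng = np.random.default_rng(_CALIBRATION_SEED)
    cov = _draw_covariates(config, rng, _CALIBRATION_DRAWS)
    eta = _linear_predictor(config, cov)
    target = config.baseline_prevalence

    def gap(b0):
        return _sigmoid(b0 + eta).mean() - target

    return float(brentq(gap, -30.0, 10.0, xtol=1e-10))


def generate_histories(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Fast path: one row per woman with demographics, latent profile,
    violence flag/code and the 29 history indicators. Deterministic given
    config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_women
    cov = _draw_covariates(config, rng, n)
    b0 = calibrated_intercept(config)
    p = _sigmoid(b0 + _linear_predictor(config, cov))
    flag = rng.random(n) < p

    # violence-code emission: flag <=> code presence, exactly
    profile = cov["profile"]
    code_cat = np.full(n, -1)
    for k, prof in enumerate(config.community_profiles):
        code_cat[profile == k] = category_id(VIOLENCE_CODES[prof.violence_code])
    no_prof_flagged = (profile < 0) & flag
    if no_prof_flagged.any():
        code_cat[no_prof_flagged] = rng.choice(9, size=int(no_prof_flagged.sum()))
    ind = cov["indicators"]
    rows = np.flatnonzero(flag)
    ind[rows, code_cat[rows]] = True
    if config.extra_violence_code_prob > 0:
        extra = rng.random((n, 9)) < config.extra_violence_code_prob
        ind[:, :9] |= extra & flag[:, None]

    df = pd.DataFrame(ind, columns=list(CATEGORIES))
    df.insert(0, "woman_id", [f"W{i:07d}" for i in range(n)])
    df.insert(1, "age_group", pd.Categorical.from_codes(cov["age_idx"], categories=list(AGE_GROUPS)))
    df.insert(2, "nationality", np.where(cov["foreign"], "foreign", "italian"))
    df.insert(3, "residence", np.where(cov["metro"], "metro_rome", "outside"))
    profile_names = np.array(["none"] + [p_.name for p_ in config.community_profiles])
    df.insert(4, "latent_profile", profile_names[profile + 1])
    df.insert(5, "n_visits", cov["n_visits"])
    df.insert(6, "n_aggression", cov["n_aggression"])
    df.insert(7, "violence_flag", flag)
    df.insert(8, "wvv", df[list(VIOLENCE_CATEGORIES)].any(axis=1))
    return df


def generate_population(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate the women (histories truth table) of a cohort."""
    return SyntheticCohort(women=generate_histories(config, seed=seed), truth=config)


# ---------------------------------------------------------------------------
# visit materialization
# ---------------------------------------------------------------------------

def generate_visits(cohort: SyntheticCohort, config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Materialize visit rows realizing each woman's history indicators.

    Diagnosis categories occur on a truncated-binomial (>= 1) number of
    visits; each trauma-place category occupies one dedicated non-aggression
    visit; the missing-diagnosis category occupies one dedicated
    left-without-visit row with no codes; violence codes are emitted at the
    index aggression visit. Extra non-aggression visits are appended when a
    woman's presences need more hosts than her drawn visit count provides.
    """
    config = config or cohort.truth
    women = cohort.women
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1_000_003)

    year0, year1 = config.period
    span_days = (pd.Timestamp(f"{year1}-12-31") - pd.Timestamp(f"{year0}-01-01")).days
    # 365 days/year keeps every offset inside the calendar look-back window
    # regardless of where leap days fall
    lookback_days = config.lookback_years * 365

    trauma_place_of = {
        "trauma_work_school": "work_school",
        "trauma_road": "road",
        "trauma_home": "home",
        "trauma_other": "other",
    }
    diag_cats = [c for c in EMITTABLE
                 if c not in trauma_place_of and c != "missing_diagnosis"]

    records: list[dict] = []
    ind_cols = {c: women[c].to_numpy() for c in CATEGORIES}
    n_visits_arr = women["n_visits"].to_numpy()
    n_agg_arr = women["n_aggression"].to_numpy()
    flag_arr = women["violence_flag"].to_numpy()
    age_groups = women["age_group"].astype(str).to_numpy()
    nats = women["nationality"].to_numpy()
    residences = women["residence"].to_numpy()
    ids = women["woman_id"].to_numpy()
    profiles = women["latent_profile"].to_numpy()
    prof_by_name = {p.name: p for p in config.community_profiles}

    for w in range(len(women)):
        present = [c for c in CATEGORIES if ind_cols[c][w]]
        n_traumas = sum(1 for c in present if c in trauma_place_of)
        has_missing = "missing_diagnosis" in present
        nv = int(n_visits_arr[w])
        na = int(n_agg_arr[w])
        needed = na + n_traumas + int(has_missing)
        nv = max(nv, needed)

        # visit slots: 0 = index aggression (latest date), then the rest
        is_agg = np.zeros(nv, dtype=bool)
        is_agg[:na] = True
        index_date = pd.Timestamp(f"{year0}-01-01") + pd.Timedelta(
            days=int(rng.integers(lookback_days, span_days + 1))
        )
        offsets = np.concatenate(
            [[0], rng.integers(0, lookback_days + 1, size=nv - 1)]
        )
        dates = [index_date - pd.Timedelta(days=int(d)) for d in offsets]

        codes: list[list[str]] = [[] for _ in range(nv)]
        places = ["none"] * nv
        left_without = np.zeros(nv, dtype=bool)

        non_agg = list(np.flatnonzero(~is_agg))
        rng.shuffle(non_agg)
        host_iter = iter(non_agg)
        if has_missing:
            left_without[next(host_iter)] = True
        for c in present:
            if c in trauma_place_of:
                places[next(host_iter)] = trauma_place_of[c]

        open_slots = np.flatnonzero(~left_without)
        pv = config.per_visit_probs(
            None if profiles[w] == "none"
            else config.community_profiles.index(prof_by_name[profiles[w]])
        )
        for c in present:
            if c in diag_cats:
                p = pv[category_id(c)]
                m = len(open_slots)
                k = 1 + rng.binomial(m - 1, p) if m > 1 else 1
                hosts = rng.choice(open_slots, size=min(k, m), replace=False)
                for h in hosts:
                    codes[h].append(REPRESENTATIVE_CODES[c])
        if flag_arr[w]:
            for c in present:
                if c in VIOLENCE_CATEGORIES:
                    codes[0].append(_CODE_OF_VIOLENCE_CAT[c])

        for v in range(nv):
            lw = bool(left_without[v])
            triage = rng.choice(["green", "yellow", "white", "red"], p=[0.75, 0.12, 0.1, 0.03])
            records.append({
                "woman_id": ids[w],
                "visit_date": dates[v].date().isoformat(),
                "icd9_codes": "" if lw else ";".join(codes[v]),
                "trauma_place": places[v],
                "aggression_flag": bool(is_agg[v]),
                "arrival": rng.choice(["self", "ambulance", "helicopter", "other"],
                                      p=[0.82, 0.16, 0.005, 0.015]),
                "outcome": "left_without_visit" if lw else
                           rng.choice(["other", "admitted", "refused_admission"],
                                      p=[0.82, 0.10, 0.08]),
                "triage": triage,
                "age_group": age_groups[w],
                "nationality": nats[w],
                "residence": residences[w],
            })

    visits = pd.DataFrame.from_records(records)
    return SyntheticCohort(women=women, truth=config, visits=visits)


# ---------------------------------------------------------------------------
# closed-form / Monte-Carlo expectations (test oracles)
# ---------------------------------------------------------------------------

def expected_cooccurrence(config: GeneratorConfig, mc_draws: int = 200_000) -> np.ndarray:
    """Expected 29x29 joint-count matrix of the per-woman co-occurrence
    counting under the generative model.

    Pairs of non-violence categories are exact: a mixture over profiles and
    the visit-count distribution of products of conditionally independent
    presence probabilities. Pairs involving a violence code depend on the
    logistic flag and are computed from a fixed-seed Monte-Carlo sample
    (deterministic for a given config).
    """
    config.validate()
    ks, pmf = config.visit_count_pmf()
    weights = [1.0 - sum(config.profile_probs), *config.profile_probs]
    E = np.zeros((N_CATEGORIES, N_CATEGORIES))
    emit_ids = np.array([category_id(c) for c in EMITTABLE])
    rep = category_id("repeated_aggression")
    for k, w in enumerate(weights):
        if w <= 0:
            continue
        prof = None if k == 0 else k - 1
        pv = config.per_visit_probs(prof)
        a = config.repeat_prob_for(prof)
        # presence probs per visit-count value
        q = 1.0 - (1.0 - pv[None, :]) ** ks[:, None]          # (len(ks), 29)
        q[:, rep] = 1.0 - (1.0 - a) ** (ks - 1)
        ids = np.append(emit_ids, rep)
        qe = q[:, ids]
        # sum_n pmf_n * q_i(n) q_j(n)
        joint = np.einsum("n,ni,nj->ij", pmf, qe, qe)
        block = np.zeros_like(E)
        block[np.ix_(ids, ids)] = joint
        E += w * block
    E[np.diag_indices_from(E)] = 0.0
    E *= config.n_women

    # violence-code rows via Monte Carlo on the indicator model
    sub = replace(config, n_women=mc_draws, seed=_CALIBRATION_SEED + 1)
    hist = generate_histories(sub)
    X = hist[list(CATEGORIES)].to_numpy()
    joint_mc = (X.T.astype(float) @ X.astype(float)) / mc_draws * config.n_women
    vio = [category_id(c) for c in VIOLENCE_CATEGORIES]
    for i in vio:
        E[i, :] = joint_mc[i, :]
        E[:, i] = joint_mc[:, i]
    E[np.diag_indices_from(E)] = 0.0
    return E


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write visits as CSV and the per-woman truth (latent profile, violence
    flag) as JSON under ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort.visits is not None:
        cohort.visits.to_csv(out / "visits.csv", index=False)
    cohort.women.to_csv(out / "histories_truth.csv", index=False)
    truth = {
        str(r.woman_id): {"latent_profile": str(r.latent_profile),
                          "violence_flag": bool(r.violence_flag)}
        for r in cohort.women[["woman_id", "latent_profile", "violence_flag"]].itertuples()
    }
    (out / "truth.json").write_text(json.dumps(truth))
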