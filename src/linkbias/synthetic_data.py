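"""Simulation of paired admission / microbiology files with known truth.

The generator emulates the structure of a paediatric-intensive-care audit
file linked to laboratory blood-culture records: an "admissions" file of
PICU episodes (identifiers, dates, bed-days, covariates) and a
"microbiology" file of positive blood cultures, a controlled fraction of
which truly belong to an admission (the *match rate*).  Error-free
("gold-standard") files are produced first, together with a truth table;
identifier error and missingness are then injected into the microbiology
file at a controlled rate, either completely at random or concentrated
(by a fixed ratio) on one hospital's records or on true-match records.

Identifier 5-tuples are de-duplicated across admissions, and unmatched
microbiology records never share a 5-tuple with any admission, so the
gold-standard files are perfectly linkable: every ambiguity seen by the
linkage methods is attributable to injected error alone.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "TruthTable",
    "IDENTIFIER_COLUMNS",
    "default_soundex_population",
    "generate_gold_standard",
    "inject_errors",
    "generate_scenario_suite",
    "table1_scenarios",
]

IDENTIFIER_COLUMNS = ["sex", "soundex", "dob_day", "dob_month", "dob_year"]

#: Study window for admission and specimen dates.
STUDY_START = pd.Timestamp("2003-03-01")
STUDY_END = pd.Timestamp("2010-12-31")

#: Birth-date range the DOB identifiers are drawn from (paediatric cohort).
DOB_START = pd.Timestamp("1995-01-01")
DOB_END = pd.Timestamp("2010-12-31")

ERROR_MECHANISMS = ("random", "by_hospital", "by_outcome")

# Covariate-linked sampling weights for which admissions acquire a BSI
# (log scale).  The named admission covariates must genuinely predict
# infection for the downstream imputation model to have signal, as they
# do in real PICU data: renal support and unplanned admission raise
# risk, infants are at higher risk than older children, and longer
# stays add exposure.  Hospital 2 runs a genuinely higher rate, giving
# the simulation a non-zero between-hospital difference to estimate.
_MATCH_LOGW_RENAL = 1.2
_MATCH_LOGW_UNPLANNED = 0.5
_MATCH_LOGW_AGE = {"<1m": 0.8, "1-11m": 0.4, "1-4y": 0.0, "5-15y": 0.0}
_MATCH_LOGW_BEDDAYS = 0.08  # per bed-day above the mean stay
_MATCH_LOGW_HOSPITAL2 = 0.35


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one simulation scenario.

    Defaults mirror the study design: files of 10,000 records, error and
    missingness each at 5% or 10% of records, non-random error
    concentrated 5-fold on hospital 1 or on true-match records, and 25
    replicate microbiology files per scenario.
    """

    name: str = "scenario"
    n_admissions: int = 10_000
    n_micro: int = 10_000
    match_rate: float = 0.10
    error_rate: float = 0.05
    missing_rate: Optional[float] = None  # defaults to error_rate
    error_mechanism: str = "random"
    error_ratio: float = 5.0
    n_replicates: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.match_rate < 1:
            raise ConfigurationError("match_rate must be in (0, 1)")
        miss = self.effective_missing_rate
        if self.error_rate < 0 or miss < 0 or self.error_rate + miss >= 1:
            raise ConfigurationError("error_rate + missing_rate must be in [0, 1)")
        if self.error_ratio < 1:
            raise ConfigurationError("error_ratio must be >= 1")
        if self.error_mechanism not in ERROR_MECHANISMS:
            raise ConfigurationError(
                f"error_mechanism must be one of {ERROR_MECHANISMS}"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_matches > self.n_admissions:
            raise ConfigurationError(
                "match_rate * n_micro exceeds n_admissions: matches must be "
                "distinct admissions"
            )

    @property
    def effective_missing_rate(self) -> float:
        return self.error_rate if self.missing_rate is None else self.missing_rate

    @property
    def n_matches(self) -> int:
        return int(round(self.match_rate * self.n_micro))


@dataclass
class TruthTable:
    """Gold-standard truth for one simulated file pair.

    ``pairs`` holds the true (admission_id, micro_id) matches; ``voi_gold``
    is the per-admission binary BSI indicator, 1 exactly for admissions
    appearing in ``pairs``.
    """

    pairs: pd.DataFrame  # columns: admission_id, micro_id
    voi_gold: pd.Series  # index: admission_id, values in {0, 1}

    @property
    def n_matches(self) -> int:
        return len(self.pairs)

    def matched_micro_ids(self) -> set:
        return set(self.pairs["micro_id"])


# ---------------------------------------------------------------------------
# Identifier population distributions
# ---------------------------------------------------------------------------

def default_soundex_population(n_codes: int = 500, zipf_exponent: float = 0.7):
    """Deterministic Soundex population: codes and sampling weights.

    A fixed-seed list of ``n_codes`` distinct codes with Zipf-like rank
    weights ``(rank+1)**-zipf_exponent``, emulating the skewed surname
    frequency distribution of a hospital population (sum of squared
    weights ~0.006, i.e. two random patients share a code roughly once
    in 160 draws, in line with surname-code diversity in UK cohorts).
    """
    rng = np.random.default_rng(190503)  # fixed: population, not simulation
    codes: list[str] = []
    seen = set()
    while len(codes) < n_codes:
        letter = chr(ord("A") + rng.integers(26))
        digits = rng.integers(1, 7, size=3)
        n_pad = rng.choice([0, 0, 0, 1, 2])  # some codes end in zeros
        code = letter + "".join(str(d) for d in digits[: 3 - n_pad]) + "0" * n_pad
        if code not in seen:
            seen.add(code)
            codes.append(code)
    weights = (np.arange(n_codes) + 1.0) ** (-zipf_exponent)
    return np.array(codes), weights / weights.sum()


def _draw_identifier_tuples(rng: np.random.Generator, n: int,
                            codes: np.ndarray, code_p: np.ndarray) -> pd.DataFrame:
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    sx = rng.choice(codes, size=n, p=code_p)
    span = (DOB_END - DOB_START).days + 1
    dob = DOB_START + pd.to_timedelta(rng.integers(0, span, size=n), unit="D")
    return pd.DataFrame({
        "sex": sex,
        "soundex": sx,
        "dob_day": dob.day.astype("int64"),
        "dob_month": dob.month.astype("int64"),
        "dob_year": dob.year.astype("int64"),
    })


def _tuple_keys(df: pd.DataFrame) -> pd.Series:
    return (df["sex"].astype(str) + "|" + df["soundex"].astype(str) + "|"
            + df["dob_day"].astype(str) + "|" + df["dob_month"].astype(str)
            + "|" + df["dob_year"].astype(str))


def _draw_unique_tuples(rng, n, codes, code_p, forbidden: set) -> pd.DataFrame:
    """Draw n identifier tuples, distinct from each other and from `forbidden`."""
    out = _draw_identifier_tuples(rng, n, codes, code_p)
    for _ in range(100):
        keys = _tuple_keys(out)
        bad = keys.isin(forbidden) | keys.duplicated()
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out.loc[bad, :] = _draw_identifier_tuples(rng, n_bad, codes, code_p).values
    raise RuntimeError("could not draw distinct identifier tuples")


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    # Gumbel top-k: exact sequential weighted sampling without replacement.
    gumbel = -np.log(-np.log(rng.random(len(weights))))
    return np.argsort(-(np.log(weights) + gumbel))[:k]


# ---------------------------------------------------------------------------
# Gold-standard generation
# ---------------------------------------------------------------------------

def generate_gold_standard(config: ScenarioConfig, replicate_index: int = 0):
    """Generate one error-free admissions/microbiology file pair plus truth.

    Exactly ``round(match_rate * n_micro)`` microbiology records copy the
    identifiers of a distinct admission (covariate-weighted sampling, see
    module docstring) and receive a specimen date inside that admission's
    BSI window (admission+2d .. discharge+2d); the remainder carry
    independently drawn identifiers that collide with no admission, and a
    specimen date uniform over the study window.

    Returns ``(admissions, micro, truth)`` where the files are DataFrames
    and ``truth`` is a :class:`TruthTable`.  Fully deterministic given
    ``(config.seed, replicate_index)``.
    """
    rng = np.random.default_rng([config.seed, replicate_index, 101])
    n_adm, n_mic, n_match = config.n_admissions, config.n_micro, config.n_matches
    codes, code_p = default_soundex_population()

    # --- admissions -------------------------------------------------------
    adm = _draw_unique_tuples(rng, n_adm, codes, code_p, forbidden=set())
    adm.insert(0, "admission_id", np.arange(1, n_adm + 1))
    adm.insert(1, "hospital", rng.integers(1, 3, size=n_adm))

    window = (STUDY_END - STUDY_START).days + 1
    admission_date = STUDY_START + pd.to_timedelta(
        rng.integers(0, window, size=n_adm), unit="D")
    stay = 1 + rng.poisson(4.5, size=n_adm)  # mean stay 5.5 days
    adm["admission_date"] = admission_date
    adm["discharge_date"] = admission_date + pd.to_timedelta(stay, unit="D")
    adm["bed_days"] = stay.astype(float)

    adm["age_group"] = rng.choice(
        ["<1m", "1-11m", "1-4y", "5-15y"], size=n_adm, p=[0.15, 0.35, 0.30, 0.20])
    adm["admission_type"] = rng.choice(
        ["planned", "unplanned"], size=n_adm, p=[0.4, 0.6])
    adm["admission_source"] = rng.choice(
        ["same_hospital", "other"], size=n_adm, p=[0.55, 0.45])
    adm["renal_status"] = (rng.random(n_adm) < 0.10).astype(int)
    adm["quarter_year"] = "Q" + adm["admission_date"].dt.quarter.astype(str)

    # --- which admissions acquire a BSI (covariate-weighted) --------------
    logw = (_MATCH_LOGW_RENAL * adm["renal_status"].to_numpy()
            + _MATCH_LOGW_UNPLANNED * (adm["admission_type"].to_numpy() == "unplanned")
            + adm["age_group"].map(_MATCH_LOGW_AGE).to_numpy()
            + _MATCH_LOGW_BEDDAYS * (stay - stay.mean())
            + _MATCH_LOGW_HOSPITAL2 * (adm["hospital"].to_numpy() == 2))
    matched_idx = _weighted_sample_without_replacement(rng, np.exp(logw), n_match)

    # --- microbiology file ------------------------------------------------
    matched = adm.iloc[matched_idx]
    mic_match = matched[IDENTIFIER_COLUMNS].copy()
    mic_match.insert(0, "hospital", matched["hospital"].to_numpy())
    # specimen inside [admission+2, discharge+2], both ends inclusive
    offs = rng.integers(2, stay[matched_idx] + 3)
    mic_match["specimen_date"] = (
        matched["admission_date"].to_numpy() + pd.to_timedelta(offs, unit="D"))
    mic_match["true_admission_id"] = matched["admission_id"].to_numpy()

    n_non = n_mic - n_match
    adm_keys = set(_tuple_keys(adm))
    mic_non = _draw_unique_tuples(rng, n_non, codes, code_p, forbidden=adm_keys)
    mic_non.insert(0, "hospital", rng.integers(1, 3, size=n_non))
    mic_non["specimen_date"] = STUDY_START + pd.to_timedelta(
        rng.integers(0, window, size=n_non), unit="D")
    mic_non["true_admission_id"] = pd.NA

    mic = pd.concat([mic_match, mic_non], ignore_index=True)
    mic = mic.sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(2**31))).reset_index(drop=True)
    mic.insert(0, "micro_id", np.arange(1, n_mic + 1))
    mic["true_admission_id"] = mic["true_admission_id"].astype("Int64")

    pairs = (mic.loc[mic["true_admission_id"].notna(),
                     ["true_admission_id", "micro_id"]]
             .rename(columns={"true_admission_id": "admission_id"})
             .astype({"admission_id": "int64"})
             .reset_index(drop=True))
    voi = pd.Series(0, index=pd.Index(adm["admission_id"], name="admission_id"))
    voi.loc[pairs["admission_id"].to_numpy()] = 1
    return adm, mic, TruthTable(pairs=pairs, voi_gold=voi)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def _per_record_rates(mic: pd.DataFrame, rate: float, mechanism: str,
                      ratio: float) -> np.ndarray:
    """Per-record selection probability, scaled so the expected overall
    fraction equals `rate` under differential mechanisms."""
    n = len(mic)
    if mechanism == "random" or rate == 0:
        return np.full(n, rate)
    if mechanism == "by_hospital":
        high = (mic["hospital"].to_numpy() == 1)
    elif mechanism == "by_outcome":
        high = mic["true_admission_id"].notna().to_numpy()
    else:  # pragma: no cover
        raise ConfigurationError(mechanism)
    n_high = int(high.sum())
    k = rate * n / (ratio * n_high + (n - n_high))
    if ratio * k > 1:
        raise ConfigurationError(
            "scaled per-record error probability exceeds 1; lower error_rate "
            "or error_ratio")
    return np.where(high, ratio * k, k)


def _replace_value(rng, row: pd.Series, field_name: str,
                   codes: np.ndarray, code_p: np.ndarray):
    """Draw a replacement identifier value from the population distribution,
    guaranteed different from the original and keeping the DOB a valid date."""
    orig = row[field_name]
    if field_name == "sex":
        return "F" if orig == "M" else "M"
    if field_name == "soundex":
        while True:
            v = rng.choice(codes, p=code_p)
            if v != orig:
                return v
    day = row["dob_day"]
    month = row["dob_month"]
    year = row["dob_year"]
    for _ in range(1000):
        if field_name == "dob_day":
            hi = calendar.monthrange(int(year), int(month))[1] if (
                pd.notna(year) and pd.notna(month)) else 28
            v = int(rng.integers(1, hi + 1))
        elif field_name == "dob_month":
            v = int(rng.integers(1, 13))
            if pd.notna(day) and pd.notna(year) and day > calendar.monthrange(
                    int(year), v)[1]:
                continue
        else:  # dob_year
            v = int(rng.integers(DOB_START.year, DOB_END.year + 1))
            if (pd.notna(day) and pd.notna(month)
                    and day > calendar.monthrange(v, int(month))[1]):
                continue
        if v != orig:
            return v
    raise RuntimeError("could not draw a replacement value")  # pragma: no cover


def inject_errors(mic: pd.DataFrame, config: ScenarioConfig, truth: TruthTable,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Corrupt identifier fields of a gold-standard microbiology file.

    A fraction ``error_rate`` of records (in expectation) have one
    randomly chosen identifier field replaced by a different value drawn
    from the population distribution; an independently selected fraction
    ``missing_rate`` have one randomly chosen field set to missing.
    Under ``by_hospital`` / ``by_outcome`` the selection probability is
    ``error_ratio``-fold higher for hospital-1 / true-match records, with
    rates scaled to preserve the overall expected fraction.  Value errors
    are applied before missingness.  Only identifier fields change; keys,
    dates, hospitals and the truth table are untouched.
    """
    out = mic.copy()
    for col in ("dob_day", "dob_month", "dob_year"):
        out[col] = out[col].astype("Int64")
    out["sex"] = out["sex"].astype(object)
    out["soundex"] = out["soundex"].astype(object)
    codes, code_p = default_soundex_population()
    fields = IDENTIFIER_COLUMNS

    err_p = _per_record_rates(out, config.error_rate, config.error_mechanism,
                              config.error_ratio)
    miss_p = _per_record_rates(out, config.effective_missing_rate,
                               config.error_mechanism, config.error_ratio)

    err_sel = np.flatnonzero(rng.random(len(out)) < err_p)
    for i in err_sel:
        f = fields[rng.integers(len(fields))]
        out.iat[i, out.columns.get_loc(f)] = _replace_value(
            rng, out.iloc[i], f, codes, code_p)

    miss_sel = np.flatnonzero(rng.random(len(out)) < miss_p)
    for i in miss_sel:
        f = fields[rng.integers(len(fields))]
        out.iat[i, out.columns.get_loc(f)] = pd.NA
    return out


# ---------------------------------------------------------------------------
# Scenario suites
# ---------------------------------------------------------------------------

def table1_scenarios(seed: int = 0, **overrides) -> list[ScenarioConfig]:
    """The study's 12 scenario definitions.

    Three match rates (10/50/70%) crossed with three error mechanisms at
    5% error + 5% missingness (scenarios 1-9), plus the three mechanisms
    at 10% match rate with 10% error + 10% missingness (scenarios 10-12).
    """
    rows = []
    i = 0
    for match_rate in (0.10, 0.50, 0.70):
        for mech in ERROR_MECHANISMS:
            i += 1
            rows.append((i, match_rate, 0.05, mech))
    for mech in ERROR_MECHANISMS:
        i += 1
        rows.append((i, 0.10, 0.10, mech))
    return [
        ScenarioConfig(name=f"dataset{idx:02d}", match_rate=mr, error_rate=er,
                       error_mechanism=mech, seed=seed + idx, **overrides)
        for idx, mr, er, mech in rows
    ]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def generate_scenario_suite(configs: Iterable[ScenarioConfig], out_dir) -> dict:
    """Write, per scenario, the shared gold-standard admissions file and
    truth table plus ``n_replicates`` corrupted microbiology files, with a
    JSON manifest recording configurations and seeds."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"scenarios": []}
    for cfg in configs:
        adm, mic, truth = generate_gold_standard(cfg)
        _write_csv(adm, out_dir / f"admissions_{cfg.name}.csv")
        _write_csv(truth.pairs, out_dir / f"truth_{cfg.name}.csv")
        reps = []
        for r in range(cfg.n_replicates):
            rng = np.random.default_rng([cfg.seed, r, 202])
            corrupted = inject_errors(mic, cfg, truth, rng)
            fname = f"micro_{cfg.name}_{r:02d}.csv"
            _write_csv(corrupted, out_dir / fname)
            reps.append(fname)
        entry = asdict(cfg)
        entry["replicate_files"] = reps
        manifest["scenarios"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
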