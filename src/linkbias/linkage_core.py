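"""Candidate pairs, Fellegi-Sunter match weights and match probabilities.

Every admission-microbiology record pair is summarised by its 5-field
agreement pattern (sex, soundex, DOB day/month/year; states A/D/M).  Two
scores are attached to each candidate pair:

* the composite **match weight** ``w = sum_i log2(m_i/u_i)`` over agreeing
  fields plus ``log2((1-m_i)/(1-u_i))`` over disagreeing fields (missing
  comparisons contribute 0), where ``m_i = P(agree on field i | match)``
  and ``u_i = P(agree on field i | non-match)`` are estimated directly
  from record pairs of known true status; and

* the **match probability** ``P(M | pattern)``, estimated *jointly* as the
  proportion of true matches among all pairs sharing the full pattern,
  which avoids the independence assumption between identifiers.  Patterns
  never observed in the estimation pairs fall back to an
  independence-based Bayes estimate using the prior match odds.

The default blocking rule admits every pair agreeing on the full date of
birth OR on (soundex AND sex).  Because this predicate is a function of
the agreement pattern alone, the blocked pair set contains *every* pair
whose pattern passes it, so joint pattern counts over blocked pairs equal
the counts over the full cross product for those patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .identifiers import FIELDS

__all__ = [
    "FieldProbabilities",
    "JointMatchProbabilities",
    "PairSet",
    "EstimationError",
    "pattern_passes_blocking",
    "estimate_field_probabilities",
    "match_weight",
    "pattern_weights",
    "estimate_joint_match_probabilities",
    "generate_candidate_pairs",
    "build_estimation_pairs",
    "attach_scores",
]

_EPS = 1e-4  # clipping bound for m/u estimates

_ID_COLS = ["sex", "soundex", "dob_day", "dob_month", "dob_year"]


class EstimationError(ValueError):
    """Raised when probabilities cannot be estimated from the given pairs."""


@dataclass(frozen=True)
class FieldProbabilities:
    """Per-field conditional agreement probabilities (order: FIELDS)."""

    m: tuple  # P(agree | match), one per field
    u: tuple  # P(agree | non-match), one per field

    def __post_init__(self):
        for v in (*self.m, *self.u):
            if not 0 < v < 1:
                raise ValueError("m and u must lie strictly in (0, 1)")
        if len(self.m) != len(FIELDS) or len(self.u) != len(FIELDS):
            raise ValueError(f"expected {len(FIELDS)} fields")

    @property
    def agree_weights(self) -> np.ndarray:
        return np.log2(np.array(self.m) / np.array(self.u))

    @property
    def disagree_weights(self) -> np.ndarray:
        return np.log2((1 - np.array(self.m)) / (1 - np.array(self.u)))


@dataclass
class PairSet:
    """Candidate pairs with patterns, scores and provenance."""

    df: pd.DataFrame
    blocking: str = "default"
    field_probs: Optional[FieldProbabilities] = None

    def __len__(self):
        return len(self.df)


def _pattern_strings(left: pd.DataFrame, right: pd.DataFrame) -> np.ndarray:
    """Vectorised 5-char A/D/M pattern for row-aligned identifier frames."""
    n = len(left)
    states = np.empty((n, len(_ID_COLS)), dtype="U1")
    for j, col in enumerate(_ID_COLS):
        a = left[col].to_numpy(object)
        b = right[col].to_numpy(object)
        miss = pd.isna(a) | pd.isna(b)
        eq = np.zeros(n, bool)
        ok = ~miss
        eq[ok] = a[ok] == b[ok]
        states[:, j] = np.where(miss, "M", np.where(eq, "A", "D"))
    return states.view("U5").ravel() if n else np.empty(0, dtype="U5")


def compute_patterns(pairs: pd.DataFrame) -> np.ndarray:
    """Pattern strings for a merged pair frame with _adm/_mic suffixed columns."""
    left = pairs[[c + "_adm" for c in _ID_COLS]].set_axis(_ID_COLS, axis=1)
    right = pairs[[c + "_mic" for c in _ID_COLS]].set_axis(_ID_COLS, axis=1)
    return _pattern_strings(left, right)


def pattern_passes_blocking(pattern: str) -> bool:
    """Default blocking predicate: full-DOB agreement OR (soundex AND sex)."""
    return pattern[2:5] == "AAA" or pattern[:2] == "AA"


# ---------------------------------------------------------------------------
# m/u estimation and weights
# ---------------------------------------------------------------------------

def estimate_field_probabilities(pairs: pd.DataFrame) -> FieldProbabilities:
    """Estimate m and u by direct counting on pairs of known true status.

    ``pairs`` needs columns ``pattern`` (5-char A/D/M string) and
    ``true_status`` (boolean).  Missing comparisons are excluded from the
    denominators; estimates are clipped to ``[1e-4, 1 - 1e-4]``.
    """
    if "true_status" not in pairs or pairs["true_status"].isna().any():
        raise EstimationError("all pairs must carry a known true status")
    status = pairs["true_status"].to_numpy(bool)
    if not status.any() or status.all():
        raise EstimationError("need at least one match and one non-match")
    pats = pairs["pattern"].to_numpy("U5").view("U1").reshape(len(pairs), -1)
    m, u = [], []
    for j in range(len(FIELDS)):
        col = pats[:, j]
        for mask, dest in ((status, m), (~status, u)):
            obs = mask & (col != "M")
            if not obs.any():
                dest.append(0.5)  # field never observed: uninformative
                continue
            dest.append(float(np.clip((col[obs] == "A").mean(), _EPS, 1 - _EPS)))
    return FieldProbabilities(m=tuple(m), u=tuple(u))


def match_weight(pattern: str, fp: FieldProbabilities) -> float:
    """Composite log2 match weight of one agreement pattern."""
    w = 0.0
    aw, dw = fp.agree_weights, fp.disagree_weights
    for j, s in enumerate(pattern):
        if s == "A":
            w += aw[j]
        elif s == "D":
            w += dw[j]
    return float(w)


def pattern_weights(patterns: np.ndarray, fp: FieldProbabilities) -> np.ndarray:
    """Vectorised :func:`match_weight` over an array of pattern strings."""
    pats = np.asarray(patterns, dtype="U5").view("U1").reshape(len(patterns), -1)
    w = np.zeros(len(patterns))
    for j in range(len(FIELDS)):
        col = pats[:, j]
        w += np.where(col == "A", fp.agree_weights[j],
                      np.where(col == "D", fp.disagree_weights[j], 0.0))
    return w


# ---------------------------------------------------------------------------
# Joint match probabilities
# ---------------------------------------------------------------------------

@dataclass
class JointMatchProbabilities:
    """P(M | pattern) map with an independence-Bayes fallback.

    For patterns observed during estimation the probability is the direct
    proportion of true matches among pairs with that pattern.  For unseen
    patterns, ``P = R / (1 + R)`` with ``R = prior_odds * 2**weight``.
    """

    table: dict
    field_probs: FieldProbabilities
    prior_odds: float

    def lookup(self, pattern: str) -> float:
        p = self.table.get(pattern)
        if p is not None:
            return p
        r = self.prior_odds * 2.0 ** match_weight(pattern, self.field_probs)
        return r / (1.0 + r)

    def lookup_many(self, patterns: np.ndarray) -> np.ndarray:
        return np.array([self.lookup(p) for p in np.asarray(patterns)])


def estimate_joint_match_probabilities(
    pairs: pd.DataFrame, fp: FieldProbabilities
) -> JointMatchProbabilities:
    """Estimate P(M | pattern) jointly from pairs of known true status."""
    if len(pairs) == 0:
        raise EstimationError("empty pair set")
    if pairs["true_status"].isna().any():
        raise EstimationError("all pairs must carry a known true status")
    status = pairs["true_status"].astype(bool)
    grp = status.groupby(pairs["pattern"].to_numpy())
    table = (grp.sum() / grp.count()).to_dict()
    n_match = int(status.sum())
    n_non = int((~status).sum())
    if n_match == 0 or n_non == 0:
        raise EstimationError("need both matches and non-matches")
    return JointMatchProbabilities(table=table, field_probs=fp,
                                   prior_odds=n_match / n_non)


# ---------------------------------------------------------------------------
# Candidate-pair generation
# ---------------------------------------------------------------------------

def _prep(df: pd.DataFrame, keep: list, suffix: str) -> pd.DataFrame:
    out = df[keep].copy()
    return out.rename(columns={c: c + suffix for c in _ID_COLS})


def generate_candidate_pairs(
    admissions: pd.DataFrame,
    micro: pd.DataFrame,
    blocking: str = "default",
    truth=None,
) -> PairSet:
    """Build the candidate pair set with agreement patterns attached.

    ``blocking="default"`` emits every pair agreeing on the full DOB or on
    (soundex AND sex); ``blocking="none"`` emits the full cross product
    (records with all identifiers missing then appear with weight 0).
    When a truth table is supplied a boolean ``true_status`` column is
    attached.  Weights and match probabilities are attached separately by
    :func:`attach_scores` once probabilities have been estimated.
    """
    adm = _prep(admissions, ["admission_id", "admission_date"] + _ID_COLS, "_adm")
    mic = _prep(micro, ["micro_id", "specimen_date"] + _ID_COLS, "_mic")

    if blocking == "none":
        pairs = adm.merge(mic, how="cross")
    elif blocking == "default":
        parts = []
        for adm_keys, mic_keys in (
            (["dob_day_adm", "dob_month_adm", "dob_year_adm"],
             ["dob_day_mic", "dob_month_mic", "dob_year_mic"]),
            (["soundex_adm", "sex_adm"], ["soundex_mic", "sex_mic"]),
        ):
            a = adm.dropna(subset=adm_keys)
            b = mic.dropna(subset=mic_keys)
            parts.append(a.merge(b, left_on=adm_keys, right_on=mic_keys))
        pairs = pd.concat(parts, ignore_index=True).drop_duplicates(
            subset=["admission_id", "micro_id"], ignore_index=True)
    else:
        raise ValueError(f"unknown blocking rule {blocking!r}")

    pairs["pattern"] = compute_patterns(pairs)
    pairs = pairs[["admission_id", "micro_id", "admission_date",
                   "specimen_date", "pattern"]].copy()
    if truth is not None:
        key = pairs["admission_id"].astype(str) + "|" + pairs["micro_id"].astype(str)
        true_key = set(truth.pairs["admission_id"].astype(str) + "|"
                       + truth.pairs["micro_id"].astype(str))
        pairs["true_status"] = key.isin(true_key)
    return PairSet(df=pairs, blocking=blocking)


def attach_scores(pairs: PairSet, fp: FieldProbabilities,
                  jmp: Optional[JointMatchProbabilities] = None) -> PairSet:
    """Attach weights (and, given a joint table, match probabilities)."""
    df = pairs.df.copy()
    pats = df["pattern"].to_numpy("U5")
    # score each distinct pattern once
    uniq, inv = np.unique(pats, return_inverse=True)
    df["weight"] = pattern_weights(uniq, fp)[inv]
    if jmp is not None:
        df["match_probability"] = jmp.lookup_many(uniq)[inv]
    return PairSet(df=df, blocking=pairs.blocking, field_probs=fp)


def build_estimation_pairs(admissions: pd.DataFrame, micro: pd.DataFrame,
                           truth, rng: np.random.Generator,
                           n_nonmatch_sample: int = 50_000) -> pd.DataFrame:
    """Truth-labelled pairs for m/u estimation.

    All true-match pairs, plus a uniform random sample of non-match pairs
    (unconditional on blocking, so u is estimated over the full cross
    product rather than over blocked pairs only).
    """
    adm_ids = admissions["admission_id"].to_numpy()
    mic_ids = micro["micro_id"].to_numpy()
    true_key = set(truth.pairs["admission_id"].astype(str) + "|"
                   + truth.pairs["micro_id"].astype(str))

    ai = rng.integers(0, len(adm_ids), size=n_nonmatch_sample)
    mi = rng.integers(0, len(mic_ids), size=n_nonmatch_sample)
    samp = pd.DataFrame({"admission_id": adm_ids[ai], "micro_id": mic_ids[mi]})
    key = samp["admission_id"].astype(str) + "|" + samp["micro_id"].astype(str)
    samp = samp[~key.isin(true_key)]

    frames = []
    for ids, status in ((truth.pairs, True), (samp, False)):
        merged = (ids.merge(admissions[["admission_id"] + _ID_COLS]
                            .rename(columns={c: c + "_adm" for c in _ID_COLS}),
                            on="admission_id")
                  .merge(micro[["micro_id"] + _ID_COLS]
                         .rename(columns={c: c + "_mic" for c in _ID_COLS}),
                         on="micro_id"))
        frames.append(pd.DataFrame({
            "admission_id": merged["admission_id"],
            "micro_id": merged["micro_id"],
            "pattern": compute_patterns(merged),
            "true_status": status,
        }))
    return pd.concat(frames, ignore_index=True)
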