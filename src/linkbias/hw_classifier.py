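"""Highest-weight link classification with data-driven thresholds.

Candidate pairs are ordered by descending match weight and accepted
greedily while both records are unclaimed and the weight is at least the
cut-off threshold; each admission links to at most one microbiology
record and vice versa.  Weight ties between microbiology candidates for
one admission are broken toward the earliest specimen date, ties of one
microbiology record across admissions toward the earliest admission
date, and any remaining ties toward the smallest record keys, so
classification is fully deterministic.

The threshold is chosen on a subset of records of known true status
(default 10% of microbiology records, stratified by match status) by
scanning every distinct observed weight and counting false-matches and
missed-matches, minimising either their sum or their absolute difference
(the "net" effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage_core import PairSet

__all__ = [
    "LinkDecisionSet",
    "classify_highest_weight",
    "count_linkage_errors",
    "select_threshold",
]


@dataclass
class LinkDecisionSet:
    """Accepted links: one row per linked admission.

    ``links`` has columns admission_id, micro_id, weight.  ``voi(ids)``
    returns the binary linked-BSI indicator over an admission index.
    """

    links: pd.DataFrame
    threshold: float

    def voi(self, admission_ids) -> pd.Series:
        idx = pd.Index(admission_ids, name="admission_id")
        return pd.Series(idx.isin(self.links["admission_id"]).astype(int),
                         index=idx)


def _greedy_accept(df: pd.DataFrame) -> pd.DataFrame:
    """Run the deterministic greedy mutual-best scan over all pairs.

    Because pairs are processed in a fixed order and each decision
    depends only on earlier (higher-ranked) decisions, the accepted set
    at any threshold t is exactly the subset of this full scan's
    accepted pairs with weight >= t.
    """
    order = df.sort_values(
        by=["weight", "specimen_date", "admission_date", "admission_id",
            "micro_id"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    )
    adm = order["admission_id"].to_numpy()
    mic = order["micro_id"].to_numpy()
    used_a: set = set()
    used_m: set = set()
    keep = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        a, m = adm[i], mic[i]
        if a not in used_a and m not in used_m:
            used_a.add(a)
            used_m.add(m)
            keep[i] = True
    return order.loc[keep, ["admission_id", "micro_id", "weight"]]


def classify_highest_weight(pairs: PairSet, threshold: float) -> LinkDecisionSet:
    """Accept greedily, by descending weight, pairs with weight >= threshold."""
    df = pairs.df
    if "weight" not in df:
        raise ValueError("pairs carry no weights; attach scores first")
    eligible = df[df["weight"] >= threshold]
    links = _greedy_accept(eligible).reset_index(drop=True)
    return LinkDecisionSet(links=links, threshold=threshold)


def count_linkage_errors(decisions: LinkDecisionSet, truth) -> tuple[int, int]:
    """(false_matches, missed_matches) of a decision set against truth.

    A false-match is an accepted pair that is not a true pair; a
    missed-match is a true pair whose admission is not linked to that
    microbiology record.  An admission linked to the wrong record
    therefore counts as one of each.
    """
    acc = set(zip(decisions.links["admission_id"], decisions.links["micro_id"]))
    true_pairs = set(zip(truth.pairs["admission_id"], truth.pairs["micro_id"]))
    false_matches = len(acc - true_pairs)
    missed_matches = len(true_pairs - acc)
    return false_matches, missed_matches


def _subset_micro_ids(pairs_df: pd.DataFrame, truth, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample microbiology records stratified by true match status."""
    mic_ids = pd.unique(pairs_df["micro_id"])
    matched = truth.matched_micro_ids()
    chosen = []
    for ids in (np.array([m for m in mic_ids if m in matched]),
                np.array([m for m in mic_ids if m not in matched])):
        k = int(round(fraction * len(ids)))
        if len(ids):
            chosen.append(rng.choice(ids, size=min(max(k, 1), len(ids)),
                                     replace=False))
    return np.concatenate(chosen) if chosen else np.empty(0, dtype=int)


def select_threshold(pairs: PairSet, truth, criterion: str = "sum",
                     subset_fraction: float = 0.10,
                     rng: np.random.Generator | None = None,
                     subset_micro_ids=None):
    """Choose the weight threshold minimising linkage error on a subset.

    Candidate thresholds are the distinct weights among the subset's
    pairs plus +inf; for each, greedy classification errors against the
    subset truth are counted and the chosen criterion ("sum" =
    false + missed, "net" = |false - missed|) is minimised, ties broken
    toward the higher threshold (fewer false-matches).

    Returns ``(threshold, report)`` where ``report`` is a DataFrame with
    columns candidate_threshold, false_matches, missed_matches,
    sum_errors, net_errors.
    """
    if criterion not in ("sum", "net"):
        raise ValueError("criterion must be 'sum' or 'net'")
    df = pairs.df
    if subset_micro_ids is None:
        if rng is None:
            rng = np.random.default_rng(0)
        subset_micro_ids = _subset_micro_ids(df, truth, subset_fraction, rng)
    subset_micro_ids = np.asarray(subset_micro_ids)
    sub = df[df["micro_id"].isin(subset_micro_ids)]
    truth_sub = truth.pairs[truth.pairs["micro_id"].isin(subset_micro_ids)]
    if len(truth_sub) == 0:
        raise ValueError("truth subset contains no matches")

    accepted = _greedy_accept(sub)
    true_key = set(zip(truth_sub["admission_id"], truth_sub["micro_id"]))
    acc_true = np.array([
        (a, m) in true_key
        for a, m in zip(accepted["admission_id"], accepted["micro_id"])
    ], dtype=bool) if len(accepted) else np.empty(0, bool)
    acc_w = accepted["weight"].to_numpy()

    thresholds = np.concatenate([np.unique(sub["weight"]), [np.inf]])
    rows = []
    n_truth = len(truth_sub)
    for t in thresholds:
        at = acc_w >= t
        fm = int((at & ~acc_true).sum())
        correct = int((at & acc_true).sum())
        mm = n_truth - correct
        rows.append((t, fm, mm, fm + mm, abs(fm - mm)))
    report = pd.DataFrame(rows, columns=[
        "candidate_threshold", "false_matches", "missed_matches",
        "sum_errors", "net_errors"])

    key = "sum_errors" if criterion == "sum" else "net_errors"
    best = report[report[key] == report[key].min()]
    threshold = float(best["candidate_threshold"].max())
    return threshold, report
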