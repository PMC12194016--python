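"""Structuredness, performance, practice and motivation scores.

Per-participant statistics derived from the click streams:

* **rule-jump score** — executed between-rule transitions minus the
  transitions necessary for the correct solution (``n_rules - 1``,
  the minimum needed to click every rule's symbols grouped); negative
  values are possible for abandoned items.
* **test score** — number of correctly solved analysed items.
* **acceleration** (``delta_m``) — mean of a timing measure over the
  first third of the test minus the last third; positive = speeding up.
* **RtD slope** — intraindividual regression slope of item time on item
  difficulty (1 - P); standardized within participant by default so the
  statistic is scale-free (raw-seconds slope available).
* **IAP** — incomplete attempt propensity: an item is an incomplete
  attempt when it is terminated before every rule was attempted (>= 1
  click on the rule's symbol group); decomposed into a participant-level
  global mean and an item-level group-mean-centred current part.

Classical item statistics (difficulty P, item-rest correlation,
Cronbach's alpha) for the correctness matrix round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_logs import ItemLog, ItemSpec, SessionLog
from .lft_extraction import ExtractionConfig, participant_item_table, participant_lfts, segment_by_rule

__all__ = [
    "ItemStats",
    "rule_jump_score",
    "test_score",
    "item_stats",
    "acceleration",
    "rtd_slope",
    "iap_indicator",
    "iap_decompose",
    "build_feature_table",
]


@dataclass(frozen=True)
class ItemStats:
    """Classical test-theory statistics of a correctness matrix."""

    p: pd.Series  # item difficulty (proportion correct)
    item_rest_r: pd.Series  # correlation of item with rest score
    cronbach_alpha: float


def rule_jump_score(item_log: ItemLog, item_spec: ItemSpec) -> int:
    """Executed minus necessary rule jumps for one item log.

    Executed jumps count consecutive click pairs whose rules differ;
    necessary jumps are ``n_rules - 1``.  Abandoned items with few clicks
    can thus score negative.
    """
    seq = segment_by_rule(item_log, item_spec)
    executed = sum(1 for (r0, _), (r1, _) in zip(seq, seq[1:]) if r0 != r1)
    return executed - (item_spec.n_rules - 1)


def test_score(session: SessionLog, item_bank: Sequence[ItemSpec]) -> int:
    """Number of correctly solved analysed (>= 2 rules) items."""
    bank = {it.item_id: it for it in item_bank}
    return sum(
        1
        for log in session.item_logs
        if bank[log.item_id].analyzed and log.correct
    )


def item_stats(correct: pd.DataFrame) -> ItemStats:
    """P, item-rest correlation and Cronbach's alpha of a binary matrix.

    ``correct`` is participants x items (0/1).  Alpha follows the
    variance form ``k/(k-1) * (1 - sum item variances / variance of
    total)``.  Zero-variance items get a missing item-rest correlation
    (with a warning); alpha requires at least two items.
    """
    x = correct.astype(float)
    n, k = x.shape
    if n < 2:
        raise ValueError("item statistics require at least 2 participants")
    if k < 2:
        raise ValueError("Cronbach's alpha requires at least 2 items")
    p = x.mean(axis=0)
    total = x.sum(axis=1)
    rest_r = {}
    for col in x.columns:
        rest = total - x[col]
        if x[col].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            warnings.warn(f"item {col!r} has zero variance; item-rest r undefined",
                          stacklevel=2)
            rest_r[col] = np.nan
        else:
            rest_r[col] = float(np.corrcoef(x[col], rest)[0, 1])
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = total.var(ddof=1)
    if total_var == 0:
        alpha = np.nan
    else:
        alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return ItemStats(p=p, item_rest_r=pd.Series(rest_r), cronbach_alpha=float(alpha))


def acceleration(values: Sequence[float]) -> float:
    """First-third minus last-third mean of a position-ordered series.

    Thirds are the head and tail ``floor(n/3)`` items (middle discarded);
    for a 22-item test that is 7 and 7.  NaNs are ignored within each
    third.  Positive values mean the participant sped up.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("acceleration requires at least 3 position-ordered values")
    third = len(v) // 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN thirds -> NaN
        return float(np.nanmean(v[:third]) - np.nanmean(v[-third:]))


def rtd_slope(
    tot: Sequence[float],
    difficulty: Sequence[float],
    standardized: bool = True,
) -> float:
    """Response-to-difficulty slope: item time regressed on difficulty.

    With ``standardized=True`` both variables are z-scored within the
    participant, so the slope equals the Pearson correlation and is
    comparable across participants.  Requires >= 3 items and difficulty
    variance; returns NaN (with a warning) if the time values do not
    vary.
    """
    y = np.asarray(tot, dtype=float)
    x = np.asarray(difficulty, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("RtD slope requires at least 3 items")
    if np.ptp(x) == 0:
        warnings.warn("zero difficulty variance; RtD slope undefined", stacklevel=2)
        return float("nan")
    if standardized:
        if np.ptp(y) == 0:
            warnings.warn("zero time variance; RtD slope undefined", stacklevel=2)
            return float("nan")
        y = (y - y.mean()) / y.std(ddof=1)
        x = (x - x.mean()) / x.std(ddof=1)
    return float(np.polyfit(x, y, 1)[0])


def iap_indicator(item_log: ItemLog, item_spec: ItemSpec) -> int:
    """1 if the item was terminated before all rules were attempted.

    A rule counts as attempted when at least one click landed on its
    symbol group.  Attempt is independent of correctness.
    """
    attempted = {ev.rule_id for ev in item_log.clicks}
    return int(len(attempted) < item_spec.n_rules)


def iap_decompose(indicators: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Split IAP indicators into global and current (centred) parts.

    ``indicators`` is participants x items (0/1).  The global IAP is the
    participant mean (in [0, 1]); the current IAP is the indicator minus
    the participant's global IAP, so its mean per participant is 0.
    """
    x = indicators.astype(float)
    global_iap = x.mean(axis=1)
    current = x.sub(global_iap, axis=0)
    return global_iap, current


def build_feature_table(
    sessions: Sequence[SessionLog],
    item_bank: Sequence[ItemSpec],
    config: ExtractionConfig | None = None,
    standardized_rtd: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-participant feature table and the long table.

    Returns ``(features, long)``.  ``features`` is indexed by
    participant with columns ``score, tot, first_click, onset, inter,
    intra, rule_jump_score, accel_tot, accel_onset, accel_inter,
    accel_intra, rtd_slope, iap_global, n_items``.  ``long`` is the
    participant x item table (timings, correctness, rule jumps, IAP
    indicator and centred current IAP) used by the mixed model.
    """
    config = config or ExtractionConfig()
    bank = {it.item_id: it for it in item_bank}
    analysed = [it for it in item_bank if it.analyzed]

    long = participant_item_table(sessions, item_bank, config)
    per_log = []
    for session in sessions:
        for log in session.item_logs:
            spec = bank[log.item_id]
            if not spec.analyzed:
                continue
            per_log.append(
                {
                    "participant_id": session.participant_id,
                    "item_id": log.item_id,
                    "rule_jumps": rule_jump_score(log, spec),
                    "iap": iap_indicator(log, spec),
                }
            )
    long = long.merge(pd.DataFrame(per_log), on=["participant_id", "item_id"])
    long = long.sort_values(["participant_id", "position"]).reset_index(drop=True)

    # sample-estimated item difficulty (1 - P) for the RtD slope
    correct_wide = long.pivot(index="participant_id", columns="item_id", values="correct")
    p_items = correct_wide.mean(axis=0)
    difficulty = 1.0 - p_items

    iap_wide = long.pivot(index="participant_id", columns="item_id", values="iap")
    iap_global, iap_current = iap_decompose(iap_wide)
    long = long.merge(
        iap_current.stack().rename("iap_current").reset_index(),
        on=["participant_id", "item_id"],
    )
    long = long.merge(iap_global.rename("iap_global"), left_on="participant_id",
                      right_index=True)

    features = participant_lfts(sessions, item_bank, config)
    score = {
        s.participant_id: test_score(s, item_bank)
        for s in sessions
        if s.participant_id in features.index
    }
    features["score"] = pd.Series(score)
    features["rule_jump_score"] = long.groupby("participant_id")["rule_jumps"].mean()
    features["iap_global"] = iap_global

    accel = {}
    for pid, g in long.groupby("participant_id"):
        g = g.sort_values("position")
        accel[pid] = {
            f"accel_{m}": acceleration(g[m].to_numpy())
            for m in ("tot", "onset", "inter", "intra")
        }
        accel[pid]["rtd_slope"] = rtd_slope(
            g["tot"].to_numpy(),
            difficulty.reindex(g["item_id"]).to_numpy(),
            standardized=standardized_rtd,
        )
    features = features.join(pd.DataFrame.from_dict(accel, orient="index"))
    cols = [
        "score", "tot", "first_click", "onset", "inter", "intra",
        "rule_jump_score", "accel_tot", "accel_onset", "accel_inter",
        "accel_intra", "rtd_slope", "iap_global", "n_items",
    ]
    return features[cols], long
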