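"""Decomposition of time on task into log-file times (LFTs).

Time on task (ToT) on a construction-based matrix item splits into three
components visible in the click stream:

* **onset** — orientation time before the participant engages the first
  rule.  The raw first-click time confounds this with the first rule's
  planning time, so the onset is computed as the residual of the
  first-click time after regressing out the item's interrule time,
  recentred to the first-click grand mean (seconds scale, positive mean).
* **interrule** — gaps between consecutive clicks that belong to
  different rules (planning the next rule).
* **intrarule** — gaps between consecutive clicks within the same rule
  (executing the plan).

Per-item interrule aggregation divides the summed between-rule gaps by a
configurable denominator; the default is the number of observed
between-rule transitions, the only choice invariant to the inflation of
transition counts by extra rule jumps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_logs import ItemLog, ItemSpec, SessionLog

__all__ = [
    "ExtractionConfig",
    "ItemTimes",
    "segment_by_rule",
    "item_times",
    "residualize_onset",
    "participant_item_table",
    "participant_lfts",
]

InterDenominator = Literal["transitions", "rules", "rules-1"]
OnsetDirection = Literal["first_on_inter", "inter_on_first"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Feature-extraction options.

    ``inter_denominator``: divisor for the per-item interrule aggregate —
    observed between-rule ``transitions`` (default), ``rules`` or
    ``rules-1``.  ``onset_direction``: which variable is residualized;
    the default regresses the first-click time on the interrule time and
    keeps the residual as onset.  ``pool_residualization``: ``"pooled"``
    runs one regression over all participant-items, ``"per_item"`` one
    regression per item.
    """

    inter_denominator: InterDenominator = "transitions"
    onset_direction: OnsetDirection = "first_on_inter"
    pool_residualization: Literal["pooled", "per_item"] = "pooled"


@dataclass(frozen=True)
class ItemTimes:
    """Raw timing decomposition of one item log (seconds)."""

    tot: float
    first_click: float | None
    inter_gaps: tuple[float, ...]
    intra_gaps: tuple[float, ...]
    inter: float | None
    intra: float | None


def segment_by_rule(
    item_log: ItemLog, item_spec: ItemSpec
) -> list[tuple[str, float]]:
    """Return one ``(rule_id, t)`` per click in time order.

    Terminal events are excluded.  Every click already carries the rule
    derived from its symbol group; an unmappable symbol raises during log
    construction, so this is a straight projection.
    """
    out = []
    for ev in item_log.clicks:
        rule = ev.rule_id if ev.rule_id is not None else item_spec.rule_of(ev.symbol_id)
        out.append((rule, ev.t))
    return out


def item_times(
    item_log: ItemLog,
    item_spec: ItemSpec,
    inter_denominator: InterDenominator = "transitions",
) -> ItemTimes:
    """Decompose one item log into ToT, first-click and gap components.

    ToT is the terminal-event time and is defined for every log.  An item
    without clicks has no first-click time; an item without a same-rule
    click pair contributes no intrarule value, one without a between-rule
    pair no interrule value.
    """
    seq = segment_by_rule(item_log, item_spec)
    tot = item_log.terminal.t
    if not seq:
        return ItemTimes(tot, None, (), (), None, None)
    first_click = seq[0][1]
    inter_gaps: list[float] = []
    intra_gaps: list[float] = []
    for (r0, t0), (r1, t1) in zip(seq, seq[1:]):
        (intra_gaps if r0 == r1 else inter_gaps).append(t1 - t0)
    if inter_gaps:
        if inter_denominator == "transitions":
            denom = len(inter_gaps)
        elif inter_denominator == "rules":
            denom = item_spec.n_rules
        elif inter_denominator == "rules-1":
            denom = max(item_spec.n_rules - 1, 1)
        else:  # pragma: no cover - guarded by Literal type
            raise ValueError(f"unknown inter_denominator {inter_denominator!r}")
        inter = sum(inter_gaps) / denom
    else:
        inter = None
    intra = float(np.mean(intra_gaps)) if intra_gaps else None
    return ItemTimes(tot, first_click, tuple(inter_gaps), tuple(intra_gaps), inter, intra)


def residualize_onset(
    first_click: np.ndarray,
    inter: np.ndarray,
    direction: OnsetDirection = "first_on_inter",
) -> np.ndarray:
    """Purge the first-rule planning time from first-click times.

    OLS of ``first_click`` on ``inter`` (default direction) over the
    pooled participant-items; the onset is the residual recentred by the
    grand mean of the response so it stays on the seconds scale with a
    positive mean.  With ``direction="inter_on_first"`` the roles are
    swapped (the literal reading of the source construct definition) and
    the residualized interrule time is returned, recentred analogously.

    A constant predictor degenerates to centring (with a warning).
    """
    y, x = (
        (np.asarray(first_click, float), np.asarray(inter, float))
        if direction == "first_on_inter"
        else (np.asarray(inter, float), np.asarray(first_click, float))
    )
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("first_click and inter must be aligned 1-d vectors")
    if len(y) < 3:
        raise ValueError("need at least 3 observations to residualize")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("residualization inputs must be finite")
    if np.ptp(x) == 0:
        warnings.warn(
            "zero variance in residualization predictor; falling back to centring",
            stacklevel=2,
        )
        resid = y - y.mean()
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
    return resid + y.mean()


def participant_item_table(
    sessions: Sequence[SessionLog],
    item_bank: Sequence[ItemSpec],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Long-format timing table, one row per participant x analysed item.

    Columns: ``participant_id, item_id, position, n_rules, tot,
    first_click, inter, intra, onset, correct``.  Onset residualization
    is run over all rows with both a first click and an interrule value
    (pooled, or per item if configured); other rows get NaN onset.
    """
    config = config or ExtractionConfig()
    bank = {it.item_id: it for it in item_bank}
    rows = []
    for session in sessions:
        for log in session.item_logs:
            spec = bank[log.item_id]
            if not spec.analyzed:
                continue
            t = item_times(log, spec, config.inter_denominator)
            rows.append(
                {
                    "participant_id": session.participant_id,
                    "item_id": log.item_id,
                    "position": spec.position,
                    "n_rules": spec.n_rules,
                    "tot": t.tot,
                    "first_click": t.first_click,
                    "inter": t.inter,
                    "intra": t.intra,
                    "correct": log.correct,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        df["onset"] = pd.Series(dtype=float)
        return df
    df["onset"] = np.nan
    usable = df["first_click"].notna() & df["inter"].notna()
    if config.pool_residualization == "pooled":
        groups = [(None, df.index[usable])]
    else:
        groups = [(iid, g.index) for iid, g in df[usable].groupby("item_id")]
    for _, idx in groups:
        if len(idx) >= 3:
            df.loc[idx, "onset"] = residualize_onset(
                df.loc[idx, "first_click"].to_numpy(),
                df.loc[idx, "inter"].to_numpy(),
                config.onset_direction,
            )
    return df


def participant_lfts(
    sessions: Sequence[SessionLog],
    item_bank: Sequence[ItemSpec],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Per-participant mean ToT and LFTs over the analysed items.

    Items contributing no value to a component (e.g. no same-rule click
    pair for intrarule) are simply excluded from that component's mean.
    Participants with no analysable items are dropped with a warning.
    Returns a frame indexed by ``participant_id`` with columns
    ``tot, first_click, onset, inter, intra, n_items``.
    """
    table = participant_item_table(sessions, item_bank, config)
    if table.empty:
        warnings.warn("no analysable items in any session", stacklevel=2)
        return pd.DataFrame(
            columns=["tot", "first_click", "onset", "inter", "intra", "n_items"]
        )
    grouped = table.groupby("participant_id")
    out = grouped[["tot", "first_click", "onset", "inter", "intra"]].mean()
    out["n_items"] = grouped.size()
    missing = [
        s.participant_id for s in sessions if s.participant_id not in out.index
    ]
    if missing:
        warnings.warn(
            f"participants without analysable items dropped: {missing}", stacklevel=2
        )
    return out
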