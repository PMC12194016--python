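"""Synthetic event-log cohorts with planted strategy structure.

The generator emulates the statistical structure that the analysis stage
assumes in real construction-based matrix data:

* a two-class mixture of *structured* processors (who plan each rule
  before clicking, i.e. long between-rule planning gaps, few rule jumps)
  and *unstructured* processors (short gaps, frequent jumps);
* ability-dependent planning gaps whose practice-related decline across
  test positions correlates with ability only in the structured class;
* a mediation structure: a participant's planning-gap level drives both
  their within-rule click speed and their extra rule jumps, and extra
  jumps in turn lower the probability of solving a rule;
* first-click times that confound the global orientation (onset) latent
  with the first rule's planning gap, so that onset residualization is
  meaningful;
* item abandonment (incomplete attempt propensity, IAP) realised as a
  timeout, and difficulty-sensitive time investment (response to
  difficulty, RtD);
* right-censoring of every event at the 90-s item limit.

All gap families are log-normal: response-time components are positive
and right-skewed, and only location/scale information is available for
the real data, so the family is a modelling choice (see the methods
note).  Defaults are calibrated so that cohort descriptives reproduce
the qualitative pattern of the real clusters (unstructured: low score,
short interrule gaps, many jumps; structured: the reverse) — pattern
level only, not value-matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_logs import (
    ClickEvent,
    ItemSpec,
    SessionLog,
    build_item_log,
    default_item_bank,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_cohort", "summarize_truth"]


class ConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the cohort generator (units in comments).

    The latent model, per participant i and item j at test position p
    with rules r = 1..R:

    * onset      ``O_ij  = m_ij * LogN(log(onset_scale) - onset_decay*(p-1) + u_i^O, onset_sigma)``
      with ``u_i^O = N(0, onset_participant_sd) - onset_ability_coupling*theta_i + pace_i``
    * plan gap   ``G_ijr = m_ij * LogN(mu_i - delta_i*(p-1), gap_sigma)`` with
      ``mu_i = log(gap_scale_class) + u_i^G + pace_i - ability_gap_coupling*theta_i*[structured]``
    * intra gap  ``m_ij * max(0.2, 1 + intra_gap_coupling*z_i) * LogN(log(intra_scale) + u_i^I, intra_sigma)``
    * jumps      ``count ~ Poisson(exp(jump_log_rate_class + jump_gap_coupling*z_i))``
    * rule solve ``P = logistic(theta_i - b_jr - jump_failure_coupling*jumps
      - goal_failure_penalty*[unstructured])``

    where ``pace_i ~ N(0, pace_sd_class)`` is a general tempo factor,
    ``z_i`` standardizes the participant's gap location ``mu_i`` over the
    cohort, ``m_ij = 1 + rtd_slope_i*difficulty_j`` is the RtD budget
    multiplier, and ``delta_i = practice_decline_base +
    practice_decline_ability*theta_i`` (structured; clipped at 0) or
    ``practice_decline_base`` (unstructured).
    """

    n_participants: int = 200
    p_structured: float = 0.56
    # ability (logit scale)
    ability_mean_structured: float = 0.8
    ability_sd_structured: float = 0.8
    ability_mean_unstructured: float = -0.8
    ability_sd_unstructured: float = 0.8
    # rule difficulty prior (logit scale)
    rule_difficulty_mean: float = -0.70
    rule_difficulty_sd: float = 0.5
    # onset component (seconds / log-seconds)
    onset_scale: float = 19.0
    onset_decay: float = 0.04
    onset_sigma: float = 0.35
    onset_participant_sd: float = 0.25
    onset_ability_coupling: float = 0.20  # theta -> shorter orientation
    # general tempo: one log-normal pace factor per participant scaling all
    # of their gaps; the unstructured class is markedly more heterogeneous
    pace_sd_structured: float = 0.08
    pace_sd_unstructured: float = 0.30
    # between-rule planning gaps (seconds / log-seconds)
    gap_scale_structured: float = 16.0
    gap_scale_unstructured: float = 4.5
    gap_sigma: float = 0.45
    gap_participant_sd: float = 0.08
    ability_gap_coupling: float = 0.14  # a: theta -> shorter gaps (structured)
    practice_decline_base: float = 0.008
    practice_decline_ability: float = 0.010  # structured only
    # within-rule gaps (seconds)
    intra_scale: float = 1.3
    intra_sigma: float = 0.5
    intra_participant_sd: float = 0.30
    intra_gap_coupling: float = 0.25  # c: gap latent -> slower execution
    # extra rule-jump excursions
    jump_log_rate_structured: float = -1.2
    jump_log_rate_unstructured: float = -0.1
    jump_gap_coupling: float = 0.25  # d1: gap latent -> more jumps
    max_excursions_per_item: int = 4
    excursion_gap: float = 1.2  # seconds to/from an excursion click
    excursion_click_gap: float = 0.25  # seconds between toggle and toggle-back
    jump_failure_coupling: float = 0.2  # e: each jump lowers the solve logit
    # goal-management failure: solve-logit penalty for unstructured
    # processors on multi-rule items (they understand the single rules but
    # fail to decompose the item into rule-level subgoals)
    goal_failure_penalty: float = 0.5
    # motivation
    rtd_slope_mean: float = 0.30
    rtd_slope_sd: float = 0.20
    iap_alpha: float = 0.2
    iap_beta: float = 20.0
    # closing
    submit_delay_scale: float = 2.5
    submit_delay_sigma: float = 0.4
    time_limit: float = 90.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0.0 <= self.p_structured <= 1.0:
            raise ConfigError("p_structured must lie in [0, 1]")
        positive = [
            "ability_sd_structured",
            "ability_sd_unstructured",
            "rule_difficulty_sd",
            "onset_scale",
            "onset_sigma",
            "gap_scale_structured",
            "gap_scale_unstructured",
            "gap_sigma",
            "intra_scale",
            "intra_sigma",
            "submit_delay_scale",
            "submit_delay_sigma",
            "iap_alpha",
            "iap_beta",
            "time_limit",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        nonneg = [
            "onset_decay",
            "goal_failure_penalty",
            "pace_sd_structured",
            "pace_sd_unstructured",
            "onset_participant_sd",
            "gap_participant_sd",
            "intra_participant_sd",
            "practice_decline_base",
            "excursion_gap",
            "excursion_click_gap",
            "rtd_slope_sd",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Latents behind a generated cohort, for recovery tests.

    ``participants`` has one row per participant (class label, ability,
    latent mean onset/interrule/intrarule seconds, jump rate, practice
    decline rate, RtD slope, IAP propensity); ``rule_difficulties`` one
    row per item-rule; ``item_difficulty`` the normalized per-item
    difficulty in [0, 1] used by the RtD multiplier.
    """

    participants: pd.DataFrame
    rule_difficulties: pd.DataFrame
    item_difficulty: pd.Series


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _wrong_symbol(spec_rule, n_required: int) -> str:
    # symbol indices 1..4 per group; solution uses 1..n_required
    return f"{spec_rule.symbol_group}:{n_required + 1}"


def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    item_bank: Sequence[ItemSpec] | None = None,
) -> tuple[list[SessionLog], GroundTruth, list[ItemSpec]]:
    """Simulate a cohort of click-stream sessions plus its ground truth.

    Parameters
    ----------
    config:
        Generator settings; defaults describe the reference study design
        (200 participants, 22 multi-rule items, 90-s limit).
    seed:
        Overrides ``config.seed`` when given.
    item_bank:
        Items to administer; defaults to the packaged 22-item bank, with
        ``config.time_limit`` applied.

    Returns ``(sessions, truth, item_bank)``.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if item_bank is None:
        item_bank = default_item_bank()
    item_bank = [dc_replace(it, time_limit=config.time_limit) for it in item_bank]
    items = sorted(item_bank, key=lambda it: it.position)

    # --- per-item latents -------------------------------------------------
    rule_rows = []
    item_mean_b = {}
    for it in items:
        bs = rng.normal(config.rule_difficulty_mean, config.rule_difficulty_sd, it.n_rules)
        for r, b in zip(it.rules, bs):
            rule_rows.append({"item_id": it.item_id, "rule_id": r.rule_id, "difficulty": b})
        item_mean_b[it.item_id] = float(np.mean(bs))
    rule_diff = pd.DataFrame(rule_rows)
    b_lookup = {
        (row["item_id"], row["rule_id"]): row["difficulty"] for row in rule_rows
    }
    mb = pd.Series(item_mean_b)
    spread = mb.max() - mb.min()
    item_difficulty = (mb - mb.min()) / spread if spread > 0 else mb * 0 + 0.5

    # --- per-participant latents -----------------------------------------
    n = config.n_participants
    structured = rng.random(n) < config.p_structured
    theta = np.where(
        structured,
        rng.normal(config.ability_mean_structured, config.ability_sd_structured, n),
        rng.normal(config.ability_mean_unstructured, config.ability_sd_unstructured, n),
    )
    pace = rng.normal(0.0, 1.0, n) * np.where(
        structured, config.pace_sd_structured, config.pace_sd_unstructured
    )
    u_onset = (
        rng.normal(0.0, config.onset_participant_sd, n)
        - config.onset_ability_coupling * theta
        + pace
    )
    u_gap = rng.normal(0.0, config.gap_participant_sd, n) + pace
    u_intra = rng.normal(0.0, config.intra_participant_sd, n) + pace
    mu_gap = (
        np.where(
            structured,
            math.log(config.gap_scale_structured),
            math.log(config.gap_scale_unstructured),
        )
        + u_gap
        - config.ability_gap_coupling * theta * structured
    )
    z_gap = (mu_gap - mu_gap.mean()) / mu_gap.std() if n > 1 and mu_gap.std() > 0 else np.zeros(n)
    intra_factor = np.maximum(0.2, 1.0 + config.intra_gap_coupling * z_gap)
    jump_rate = np.exp(
        np.where(
            structured,
            config.jump_log_rate_structured,
            config.jump_log_rate_unstructured,
        )
        + config.jump_gap_coupling * z_gap
    )
    decline = np.where(
        structured,
        np.maximum(
            0.0,
            config.practice_decline_base + config.practice_decline_ability * theta,
        ),
        config.practice_decline_base,
    )
    rtd = rng.normal(config.rtd_slope_mean, config.rtd_slope_sd, n)
    iap = rng.beta(config.iap_alpha, config.iap_beta, n)

    half_sig2 = {
        "onset": config.onset_sigma**2 / 2.0,
        "gap": config.gap_sigma**2 / 2.0,
        "intra": config.intra_sigma**2 / 2.0,
    }
    truth = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:03d}" for i in range(n)],
            "strategy_class": np.where(structured, "structured", "unstructured"),
            "theta": theta,
            "latent_onset": np.exp(
                math.log(config.onset_scale) + u_onset + half_sig2["onset"]
            ),
            "latent_inter": np.exp(mu_gap + half_sig2["gap"]),
            "latent_intra": intra_factor
            * np.exp(math.log(config.intra_scale) + u_intra + half_sig2["intra"]),
            "jump_rate": jump_rate,
            "practice_decline": decline,
            "rtd_slope": rtd,
            "iap_propensity": iap,
        }
    ).set_index("participant_id", drop=False)

    # --- event streams ----------------------------------------------------
    finite_limit = math.isfinite(config.time_limit)
    sessions: list[SessionLog] = []
    for i in range(n):
        pid = truth.index[i]
        logs = []
        for it in items:
            pos = it.position
            m_ij = max(0.2, 1.0 + rtd[i] * item_difficulty[it.item_id])
            n_rules = it.n_rules
            # abandonment: attempt only a prefix of the rules
            if n_rules >= 2 and rng.random() < iap[i]:
                n_attempt = int(rng.integers(1, n_rules))
            else:
                n_attempt = n_rules
            if n_attempt >= 2 and jump_rate[i] > 0:
                n_exc = min(
                    int(rng.poisson(jump_rate[i])), config.max_excursions_per_item
                )
            else:
                n_exc = 0
            exc_blocks = (
                rng.integers(2, n_attempt + 1, n_exc) if n_exc else np.empty(0, int)
            )

            onset = m_ij * rng.lognormal(
                math.log(config.onset_scale)
                - config.onset_decay * (pos - 1)
                + u_onset[i],
                config.onset_sigma,
            )
            clicks: list[tuple[float, str]] = []
            t = onset
            for r_idx in range(n_attempt):
                rule = it.rules[r_idx]
                gap = m_ij * rng.lognormal(
                    mu_gap[i] - decline[i] * (pos - 1), config.gap_sigma
                )
                t += gap
                b = b_lookup[(it.item_id, rule.rule_id)]
                penalty = 0.0 if structured[i] else config.goal_failure_penalty
                solved = rng.random() < _logistic(
                    theta[i] - b - config.jump_failure_coupling * n_exc - penalty
                )
                k = rule.n_required_clicks
                syms = [f"{rule.symbol_group}:{s}" for s in range(1, k + 1)]
                if not solved:
                    syms[-1] = _wrong_symbol(rule, k)
                for c_idx, sym in enumerate(syms):
                    if c_idx > 0:
                        t += (
                            m_ij
                            * intra_factor[i]
                            * rng.lognormal(
                                math.log(config.intra_scale) + u_intra[i],
                                config.intra_sigma,
                            )
                        )
                    clicks.append((t, sym))
                    # excursions revisit an earlier rule right after this
                    # block's first click: one toggle plus its toggle-back
                    if c_idx == 0 and r_idx >= 1:
                        for blk in exc_blocks:
                            if blk == r_idx + 1:
                                prev = it.rules[int(rng.integers(0, r_idx))]
                                exc_sym = f"{prev.symbol_group}:4"
                                t += config.excursion_gap
                                clicks.append((t, exc_sym))
                                t += config.excursion_click_gap
                                clicks.append((t, exc_sym))
                                t += config.excursion_gap
            # terminal event
            events = [ClickEvent(ct, "click", sym) for ct, sym in clicks]
            abandoned = n_attempt < n_rules
            if abandoned:
                terminal = ClickEvent(config.time_limit, "timeout")
            else:
                t_submit = t + rng.lognormal(
                    math.log(config.submit_delay_scale), config.submit_delay_sigma
                )
                if finite_limit and t_submit > config.time_limit:
                    terminal = ClickEvent(config.time_limit, "timeout")
                else:
                    terminal = ClickEvent(t_submit, "submit")
            if finite_limit:
                events = [e for e in events if e.t <= config.time_limit]
            events.append(terminal)
            logs.append(build_item_log(pid, it, events, where=f"sim {pid}/{it.item_id}"))
        sessions.append(SessionLog(participant_id=pid, item_logs=tuple(logs)))

    return sessions, GroundTruth(truth, rule_diff, item_difficulty), items


def summarize_truth(truth: GroundTruth) -> pd.DataFrame:
    """Per-class means of the participant latents (debugging aid)."""
    df = truth.participants
    if df.empty:
        return pd.DataFrame()
    cols = [
        "theta",
        "latent_onset",
        "latent_inter",
        "latent_intra",
        "jump_rate",
        "practice_decline",
        "rtd_slope",
        "iap_propensity",
    ]
    out = df.groupby("strategy_class")[cols].mean()
    out.insert(0, "n", df.groupby("strategy_class").size())
    return out
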