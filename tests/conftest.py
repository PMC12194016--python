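"""Shared fixtures: item specs, hand-built logs, and a default cohort."""

from __future__ import annotations

import warnings

import pytest

from matrixlft import GeneratorConfig, generate_cohort
from matrixlft.io_logs import ClickEvent, ItemSpec, RuleSpec, build_item_log
from matrixlft.scores import build_feature_table

# letters name rules in hand-written click sequences
LETTERS = "ABCDE"


def make_item(
    n_rules: int = 2,
    item_id: str = "it1",
    position: int = 1,
    time_limit: float = 90.0,
    clicks_per_rule: int = 2,
) -> ItemSpec:
    groups = [f"g{i + 1}" for i in range(n_rules)]
    rules = tuple(
        RuleSpec(f"rule{i + 1}", g, clicks_per_rule) for i, g in enumerate(groups)
    )
    solution = frozenset(
        f"{g}:{k}" for g in groups for k in range(1, clicks_per_rule + 1)
    )
    return ItemSpec(item_id, position, rules, solution, time_limit)


def make_log(
    spec: ItemSpec,
    seq,
    terminal=("submit", None),
    participant_id: str = "p1",
):
    """Build an ItemLog from [(rule_letter, t), ...] plus a terminal event.

    Distinct symbols of a rule's group are cycled so that repeated visits
    to a rule do not toggle a symbol off by accident.
    """
    counters: dict[str, int] = {}
    events = []
    for letter, t in seq:
        group = spec.rules[LETTERS.index(letter)].symbol_group
        k = counters.get(letter, 0) % 4 + 1
        counters[letter] = counters.get(letter, 0) + 1
        events.append(ClickEvent(t, "click", f"{group}:{k}"))
    kind, t_term = terminal
    if t_term is None:
        t_term = (events[-1].t + 1.0) if events else spec.time_limit
    events.append(ClickEvent(t_term, kind))
    return build_item_log(participant_id, spec, events)


@pytest.fixture()
def two_rule_item() -> ItemSpec:
    return make_item(2)


@pytest.fixture()
def three_rule_item() -> ItemSpec:
    return make_item(3)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (n=200, 22 items), one fixed seed."""
    return generate_cohort(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    sessions, truth, bank = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features, long = build_feature_table(sessions, bank)
    return features, long, truth
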