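"""Marker-based neuronal typing and transcript positivity calls.

Each cell is classified from its marker-channel quantities: a typing rule
fires when the marker's dot count (or density, if the rule uses one) reaches
its threshold. No firing rule leaves the cell ``untyped``; several firing
rules are resolved by the tie policy — by default the marker with the
highest dot density wins, and an exact density tie is ``ambiguous``.
An ``exclusive`` policy instead marks every multi-marker cell ambiguous.

Positivity for the target transcript is a simple inclusive count threshold
(>= min_dots, default 1 dot).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .config import TypingRule
from .errors import ConfigError

UNTYPED = "untyped"
AMBIGUOUS = "ambiguous"


def _check_rules(rules: Sequence[TypingRule]) -> None:
    if not rules:
        raise ConfigError("at least one typing rule is required")
    labels = [r.type_label for r in rules]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate type labels in typing rules: {labels}")
    channels = [r.marker_channel for r in rules]
    if len(set(channels)) != len(channels):
        raise ConfigError(f"duplicate marker channels in typing rules: {channels}")


def classify_cell(record: Mapping, rules: Sequence[TypingRule],
                  tie_policy: str = "density") -> str:
    """Type one cell record (a dict/Series with ``{ch}_dot_count`` etc. keys)."""
    _check_rules(rules)
    if tie_policy not in ("density", "exclusive"):
        raise ConfigError(f"unknown tie_policy {tie_policy!r}")
    hits: list[TypingRule] = []
    for rule in rules:
        if rule.min_density is not None:
            value = record.get(f"{rule.marker_channel}_dot_density")
            if value is None:
                continue
            if value >= rule.min_density:
                hits.append(rule)
        else:
            value = record.get(f"{rule.marker_channel}_dot_count")
            if value is None:
                continue
            if value >= rule.min_dots:
                hits.append(rule)
    if not hits:
        return UNTYPED
    if len(hits) == 1:
        return hits[0].type_label
    if tie_policy == "exclusive":
        return AMBIGUOUS
    densities = [float(record.get(f"{r.marker_channel}_dot_density", 0.0)) for r in hits]
    top = max(densities)
    winners = [r for r, d in zip(hits, densities) if d == top]
    return winners[0].type_label if len(winners) == 1 else AMBIGUOUS


def classify_cells(df: pd.DataFrame, rules: Sequence[TypingRule],
                   tie_policy: str = "density") -> pd.DataFrame:
    """Add a ``type_label`` column to a cell table; rules on absent channels are ignored."""
    _check_rules(rules)
    usable = [r for r in rules if f"{r.marker_channel}_dot_count" in df.columns]
    if not usable:
        raise ConfigError(
            f"no typing rule matches the table's channels "
            f"(rules on {[r.marker_channel for r in rules]})"
        )
    out = df.copy()
    out["type_label"] = [
        classify_cell(row, usable, tie_policy=tie_policy)
        for row in df.to_dict("records")
    ]
    return out


def call_positive(record: Mapping, target_channel: str, min_dots: int = 1) -> bool:
    """True iff the cell has >= min_dots dots of the target transcript."""
    key = f"{target_channel}_dot_count"
    if key not in record:
        raise ConfigError(f"channel {target_channel!r} was not quantified")
    return bool(record[key] >= min_dots)


def call_positive_cells(df: pd.DataFrame, target_channel: str,
                        min_dots: int = 1) -> pd.DataFrame:
    """Add a boolean ``positive_{target_channel}`` column."""
    key = f"{target_channel}_dot_count"
    if key not in df.columns:
        raise ConfigError(f"channel {target_channel!r} was not quantified")
    out = df.copy()
    out[f"positive_{target_channel}"] = df[key] >= min_dots
    return out
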