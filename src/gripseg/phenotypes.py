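"""Handgrip scoring and cognitive T-scores / domain composites.

Handgrip strength: several dynamometer readings per hand; the per-hand
maximum is kept and overall strength is the mean of the left and right
maxima (kg).

Cognition: each test is z-standardised across the sample (sign-flipped
first for tests where higher raw scores mean worse performance, e.g.
timed trail-making tests) and mapped to T-scores, T = 50 + 10 z.  Domain
composites average the T-scores of the tests in the domain; global
cognition averages the three domain composites.  The SM-MMSE screen is
carried through raw, not T-scored.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gripseg")

#: default test battery: test -> (domain, higher_is_better)
DEFAULT_BATTERY: dict[str, tuple[str, bool]] = {
    "digit_span": ("attention", True),
    "spatial_span": ("attention", True),
    "symbol_digit": ("processing_speed", True),
    "symbol_search": ("processing_speed", True),
    "trail_making_a": ("processing_speed", False),  # time: longer is worse
    "verbal_fluency": ("executive_function", True),
    "design_fluency": ("executive_function", True),
    "trail_making_b": ("executive_function", False),
}

DOMAINS = ("attention", "processing_speed", "executive_function")


def handgrip_score(left: Iterable[float], right: Iterable[float]) -> float:
    """Mean over the two hands of the per-hand maximum reading (kg)."""
    best = []
    for hand, readings in (("left", list(left)), ("right", list(right))):
        if not readings:
            raise ValueError(f"no readings for {hand} hand")
        if any(x <= 0 for x in readings):
            raise ValueError(f"non-positive reading for {hand} hand")
        best.append(max(readings))
    return float(np.mean(best))


def tscore(raw: Iterable[float], higher_is_better: bool = True,
           name: str = "") -> np.ndarray:
    """T = 50 + 10 z with z standardised across the sample (ddof=0).

    ``higher_is_better=False`` flips the sign of z first, so larger T always
    means better performance.
    """
    x = np.asarray(list(raw), dtype=float)
    if x.size < 2:
        raise ValueError("T-scoring needs at least 2 subjects")
    sd = x.std()
    if sd == 0.0:
        label = f" for test {name!r}" if name else ""
        raise ValueError(f"zero standard deviation{label}: T-scores undefined")
    z = (x - x.mean()) / sd
    if not higher_is_better:
        z = -z
    return 50.0 + 10.0 * z


def score_battery(raw_scores: pd.DataFrame,
                  battery: Mapping[str, tuple[str, bool]] = DEFAULT_BATTERY,
                  ) -> pd.DataFrame:
    """T-score every test, then add domain composites and global cognition.

    ``raw_scores`` has one row per subject and one column per test in
    ``battery``; any ``smmse`` column passes through raw.  Returns a frame
    indexed like the input with T-score columns per test plus
    ``attention``, ``processing_speed``, ``executive_function``, ``global``
    (and ``smmse`` when present).
    """
    missing = [t for t in battery if t not in raw_scores.columns]
    if missing:
        raise ValueError(f"battery tests missing from table: {missing}")
    out = pd.DataFrame(index=raw_scores.index)
    domains: dict[str, list[str]] = {}
    for test, (domain, hib) in battery.items():
        out[test] = tscore(raw_scores[test].to_numpy(), hib, name=test)
        domains.setdefault(domain, []).append(test)
    empty = [d for d in DOMAINS if not domains.get(d)]
    if empty:
        raise ValueError(f"empty cognitive domain(s): {empty}")
    for domain, tests in domains.items():
        out[domain] = out[tests].mean(axis=1)
    out["global"] = out[[d for d in DOMAINS if d in domains]].mean(axis=1)
    if "smmse" in raw_scores.columns:
        out["smmse"] = raw_scores["smmse"].astype(float)
    return out


def read_battery_config(path) -> dict[str, tuple[str, bool]]:
    """Flat ``test = domain, direction`` key-value text -> battery mapping."""
    battery: dict[str, tuple[str, bool]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            test, _, rhs = line.partition("=")
            domain, _, direction = rhs.partition(",")
            direction = direction.strip().lower()
            if direction not in {"higher", "lower"}:
                raise ValueError(
                    f"direction for {test.strip()!r} must be 'higher' or 'lower'")
            battery[test.strip()] = (domain.strip(), direction == "higher")
    if not battery:
        raise ValueError(f"no tests found in battery config {path}")
    return battery


def write_battery_config(battery: Mapping[str, tuple[str, bool]], path) -> None:
    with open(path, "w") as fh:
        fh.write("# test = domain, higher|lower (direction of better performance)\n")
        for test, (domain, hib) in battery.items():
            fh.write(f"{test} = {domain}, {'higher' if hib else 'lower'}\n")


def drop_incomplete(data: pd.DataFrame, variables: list[str],
                    context: str = "model") -> pd.DataFrame:
    """Listwise-drop rows missing any of the named variables, logging the count."""
    sub = data[variables]
    keep = sub.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("%s: dropped %d row(s) with missing values in %s",
                    context, n_drop, variables)
    return data.loc[keep]
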