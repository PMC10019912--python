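"""Per-circle composition of trend-cluster types and dominance testing.

After every circle-by-species trend has been assigned to one of the k = 4
cluster archetypes, each survey circle is summarized by the counts of its
species falling in each cluster (optionally restricted to one habitat
guild). A chi-square goodness-of-fit test against equal proportions flags
circles whose composition departs from uniform; only those get a dominant
cluster label, so maps never color a circle on noise alone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .types import CircleSummary

log = logging.getLogger(__name__)

MIN_TEST_TOTAL = 8   # below this the chi-square approximation is unreliable
ALPHA = 0.05
K_CLUSTERS = 4


def circle_composition(assignments: pd.DataFrame, circle,
                       guild: str | None = None, k: int = K_CLUSTERS):
    """Counts and proportions of cluster labels among species at one circle.

    ``assignments`` is tidy with columns ``circle``, ``species``, ``label``
    (labels in 0..k-1) and optionally ``guild``. With a guild filter that
    leaves no species, an all-zero summary is returned (flagged by the
    zero total) rather than an error.
    """
    sub = assignments[assignments["circle"] == circle]
    if guild is not None:
        if "guild" not in sub.columns:
            raise ValueError("assignments table has no 'guild' column to filter on")
        sub = sub[sub["guild"] == guild]
    labels = sub["label"].to_numpy()
    if np.any((labels < 0) | (labels >= k)):
        raise ValueError(f"labels outside 0..{k - 1} at circle {circle}")
    counts = np.bincount(labels, minlength=k).astype(int)
    total = counts.sum()
    if total == 0:
        log.info("circle %s has no species after filtering (guild=%s)", circle, guild)
        proportions = np.zeros(k)
    else:
        proportions = counts / total
    return counts, proportions


def dominance_test(counts: np.ndarray, alpha: float = ALPHA,
                   expected: np.ndarray | None = None):
    """Chi-square proportionality test of cluster counts against uniform.

    Returns ``(statistic, p_value, dominant_label)``; the dominant label
    (argmax count, lowest index on ties) is reported only when
    ``p < alpha``. Totals below 8 are not tested (all-None return): with
    uniform expectation the expected cell count would drop below 2 and the
    chi-square approximation breaks down. ``expected`` may supply
    non-uniform null proportions (e.g. region-wide cluster frequencies).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("cluster counts must be nonnegative")
    total = counts.sum()
    if total < MIN_TEST_TOTAL:
        return None, None, None
    if expected is None:
        f_exp = np.full(counts.size, total / counts.size)
    else:
        expected = np.asarray(expected, dtype=float)
        f_exp = total * expected / expected.sum()
    stat, p = chisquare(counts, f_exp=f_exp)
    dominant = int(np.argmax(counts)) if p < alpha else None
    return float(stat), float(p), dominant


def summarize_circles(assignments: pd.DataFrame, guild: str | None = None,
                      alpha: float = ALPHA, k: int = K_CLUSTERS,
                      expected: np.ndarray | None = None) -> pd.DataFrame:
    """One :class:`CircleSummary` row per circle, as a tidy table.

    Columns: circle, the four cluster counts, proportions, chi-square
    statistic, p-value, dominant label (present only where significant),
    and whether the circle was tested at all. No multiple-testing
    correction is applied across circles — the test is used descriptively
    to decide which circles get a color on a map — and the chosen alpha is
    recorded in the table attributes.
    """
    summaries = []
    for circle in np.sort(assignments["circle"].unique()):
        counts, props = circle_composition(assignments, circle, guild=guild, k=k)
        stat, p, dom = dominance_test(counts, alpha=alpha, expected=expected)
        summaries.append(CircleSummary(
            circle=circle, counts=counts, proportions=props,
            chi_square_stat=stat, p_value=p, dominant_label=dom,
            tested=stat is not None, guild=guild,
        ))
    out = pd.DataFrame([{
        "circle": s.circle,
        **{f"count_{j}": s.counts[j] for j in range(k)},
        **{f"prop_{j}": s.proportions[j] for j in range(k)},
        "chi_square_stat": s.chi_square_stat,
        "p_value": s.p_value,
        "dominant_label": s.dominant_label,
        "tested": s.tested,
        "guild": s.guild,
    } for s in summaries])
    out.attrs["alpha"] = alpha
    out.attrs["multiple_testing_correction"] = "none"
    return out


def species_circle_map(assignments: pd.DataFrame, species) -> pd.DataFrame:
    """Per-circle cluster label for one species (the species-level map table)."""
    sub = assignments[assignments["species"] == species]
    if sub.empty:
        known = assignments["species"].unique()
        raise KeyError(f"unknown species {species!r}; table has {len(known)} species")
    return (sub[["circle", "label"]]
            .sort_values("circle")
            .reset_index(drop=True))
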