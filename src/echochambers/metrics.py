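"""Outcome measures: belief purity, extremist counts, degree histograms,
and replicate summaries.

Belief purity epsilon = 1 - (sum_i Delta_i / n_L), where Delta_i is the
absolute difference in belief means across the i-th network link and n_L
the number of links.  epsilon = 1 means every link joins agents with
identical beliefs — the signature of fully "purified" echo chambers.
Purity measures within-link similarity, not global consensus: a graph
split into internally uniform but mutually distant clusters still scores 1.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .belief import WorldTruth
from .network import SocialGraph

__all__ = [
    "UndefinedPurityError",
    "MetricsSeries",
    "belief_purity",
    "count_extremists",
    "degree_histogram",
    "replicate_summary",
]

#: Columns of a per-step metrics record.
METRIC_COLUMNS = [
    "step",
    "mean_p_h",
    "sd_p_h",
    "purity",
    "n_extremists",
    "n_links",
    "max_abs_dmu",
]


class UndefinedPurityError(ValueError):
    """Purity is undefined on a graph with no links (distinct from the value 1)."""


def belief_purity(graph: SocialGraph, beliefs: Mapping[int, float]) -> float:
    """Global belief purity epsilon over the links of ``graph``.

    Raises :class:`UndefinedPurityError` when the graph has no links.
    """
    n_links = graph.number_of_edges()
    if n_links == 0:
        raise UndefinedPurityError("purity is undefined on a graph with no links")
    total = sum(abs(beliefs[a] - beliefs[b]) for a, b in graph.edges)
    return 1.0 - total / n_links


def count_extremists(
    beliefs: Mapping[int, float] | Sequence[float],
    world: WorldTruth,
    sigma_ref: float,
    k_sd: float = 2.0,
) -> int:
    """Number of agents whose belief lies strictly further than ``k_sd``
    reference SDs from the objective truth.

    ``sigma_ref`` fixes the reference scale; using a constant (e.g. the SD
    of the initial belief-mean distribution) keeps extremist counts
    comparable across time steps.
    """
    if k_sd <= 0:
        raise ValueError(f"k_sd must be > 0, got {k_sd}")
    values = (
        np.asarray(list(beliefs.values()))
        if isinstance(beliefs, Mapping)
        else np.asarray(beliefs)
    )
    return int(np.count_nonzero(np.abs(values - world.mu_true) > k_sd * sigma_ref))


def degree_histogram(graph: SocialGraph) -> Dict[int, int]:
    """Exact histogram of node degrees; counts sum to the number of agents."""
    return dict(Counter(d for _, d in graph.degree()))


class MetricsSeries:
    """Append-only per-step population summaries.

    One row per completed step (plus the initial state at step 0); the
    degree histogram of each recorded step is kept alongside the scalar
    columns.  Expensive fields (purity, links, histogram) may be NaN/None
    on steps where snapshotting was skipped for speed.
    """

    def __init__(self) -> None:
        self._rows: List[dict] = []
        self.degree_histograms: List[Optional[Dict[int, int]]] = []

    def append(
        self,
        step: int,
        mean_p_h: float,
        sd_p_h: float,
        purity: float,
        n_extremists: int,
        n_links: float,
        max_abs_dmu: float,
        degree_hist: Optional[Dict[int, int]] = None,
    ) -> None:
        if self._rows and step != self._rows[-1]["step"] + 1:
            raise ValueError("metrics rows must be appended one step at a time")
        self._rows.append(
            dict(
                step=step,
                mean_p_h=mean_p_h,
                sd_p_h=sd_p_h,
                purity=purity,
                n_extremists=n_extremists,
                n_links=n_links,
                max_abs_dmu=max_abs_dmu,
            )
        )
        self.degree_histograms.append(degree_hist)

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=METRIC_COLUMNS)

    def to_tidy(self, replicate: Optional[int] = None) -> pd.DataFrame:
        """Long-format (step, metric, value[, replicate]) view for export."""
        tidy = self.df.melt(id_vars=["step"], var_name="metric", value_name="value")
        if replicate is not None:
            tidy["replicate"] = replicate
        return tidy


def replicate_summary(series_list: Sequence[MetricsSeries | pd.DataFrame]) -> pd.DataFrame:
    """Per-step mean and normal-approximation 95% CI across replicate runs.

    Returns a long-format frame (step, metric, mean, lo95, hi95) with the
    CI computed as mean +/- 1.96 * SE.  All replicates must have the same
    number of steps.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 replicates to summarize")
    frames = [s.df if isinstance(s, MetricsSeries) else s for s in series_list]
    n_steps = len(frames[0])
    if any(len(f) != n_steps for f in frames):
        raise ValueError("replicate series have unequal lengths")
    stacked = pd.concat(
        [f.melt(id_vars=["step"], var_name="metric", value_name="value") for f in frames]
    )
    grouped = stacked.groupby(["step", "metric"])["value"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    se = out["sd"] / np.sqrt(out["n"])
    out["lo95"] = out["mean"] - 1.96 * se
    out["hi95"] = out["mean"] + 1.96 * se
    return out[["step", "metric", "mean", "lo95", "hi95"]]
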