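"""Rank agreement between PGM distances and realized transfer performance.

A useful transferability measure should rank source datasets the same way
actual transfer learning does.  We quantify agreement with Kendall's tau
(tie-adjusted tau-b), oriented so that perfect prediction — smallest
distance paired with best transfer performance — gives tau = +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .errors import ConfigurationError, DataError
from .pgm import TransferabilityMap
from .transfer import TransferResult


@dataclass
class RankingPair:
    """Two scorings of the same items: PGM distances and a transfer metric."""

    items: list[str]
    score_a: np.ndarray  # PGM distances (smaller = more related)
    score_b: np.ndarray  # transfer metric
    higher_is_better_b: bool

    def __post_init__(self):
        self.score_a = np.asarray(self.score_a, dtype=np.float64)
        self.score_b = np.asarray(self.score_b, dtype=np.float64)
        if not (len(self.items) == len(self.score_a) == len(self.score_b)):
            raise ConfigurationError("items and scores must have equal length")
        if len(self.items) < 2:
            raise ConfigurationError("need at least 2 items to correlate rankings")
        if not (np.all(np.isfinite(self.score_a)) and np.all(np.isfinite(self.score_b))):
            raise DataError("scores contain non-finite values")


def kendall_tau(pair: RankingPair) -> float:
    """Tie-adjusted Kendall's tau-b between the two scorings, in [-1, 1].

    When ``higher_is_better_b`` the transfer metric is negated first, so a
    measure that ranks sources exactly as transfer performance does scores
    +1 and an exactly reversed ranking scores -1.
    """
    b = -pair.score_b if pair.higher_is_better_b else pair.score_b
    tau, _ = kendalltau(pair.score_a, b)
    if np.isnan(tau):
        raise DataError("Kendall's tau undefined: one of the rankings is all ties")
    return float(tau)


def correlation_experiment(tmap: TransferabilityMap, results: list[TransferResult],
                           target: str) -> float:
    """Tau between PGM distances to *target* and mean transfer metrics.

    Each result must come from fine-tuning on *target* starting from a
    source present in the map.  Orientation follows the metric: ROC-AUC is
    higher-better, RMSE lower-better.
    """
    if target not in tmap.names:
        raise ConfigurationError(f"target {target!r} not in map")
    metric_names = {r.metric_name for r in results}
    if len(metric_names) != 1:
        raise ConfigurationError(f"results mix metrics: {sorted(metric_names)}")
    items, dists, perfs = [], [], []
    for res in sorted(results, key=lambda r: r.source_name):
        if res.source_name not in tmap.names:
            raise ConfigurationError(f"source {res.source_name!r} not in map")
        items.append(res.source_name)
        dists.append(tmap.distance(target, res.source_name))
        perfs.append(res.mean)
    pair = RankingPair(items=items, score_a=np.array(dists), score_b=np.array(perfs),
                       higher_is_better_b=metric_names.pop() == "roc_auc")
    return kendall_tau(pair)


def tau_summary_table(rows: list[tuple[str, int, float]]) -> pd.DataFrame:
    """Summary table: target, number of sources, tau."""
    return pd.DataFrame(rows, columns=["target", "n_sources", "tau"])
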