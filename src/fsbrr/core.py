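"""The FSBRR selector: irrelevance filtering and approximate-redundancy removal.

The algorithm is a filter method for high-dimensional classification tables
(microarray / RNA-seq style: few instances, many features).  It proceeds in
two passes over discretized columns:

1. *Irrelevance filter.*  Each feature's relevance to the class,
   ``R_i,c = 2*IG(F_i;C)/(H(F_i)+H(C))``, is computed and features with
   ``R_i,c < tau`` are discarded.

2. *Redundancy removal.*  Survivors are sorted by descending ``R_i,c``
   (ties: ascending original index).  Walking pivots i in that order, each
   surviving later feature j is tested against two rules and removed when
   either fires:

   - rule 1: ``R_i,c - R_j,c <= delta`` and ``R_i,j >= R_i,c`` —
     j is nearly as relevant as the pivot and the pivot substitutes for it;
   - rule 2: ``delta < R_i,c - R_j,c < alpha`` and
     ``R_i,j > (R_bar + R_j,c)/2`` — j is clearly less relevant and even a
     moderate correlation with the pivot makes it expendable.

   ``R_bar`` is the mean relevance over the tau-retained set.  Removed
   features are never revisited, which is what gives the best case
   (everything redundant with the first pivot) n-1 pairwise computations
   and the worst case (nothing removed) n(n-1)/2.

A feature whose pairwise correlation with every pivot stays below both rule
thresholds is never removed, whatever its own relevance — weakly correlated
features are not substitutable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .infotheory import (
    BinningSpec,
    DiscretizedTable,
    discretize_table,
    normalized_relevance,
)

logger = logging.getLogger("fsbrr")

__all__ = [
    "FSBRRConfig",
    "RemovalRecord",
    "RelevanceProfile",
    "SelectionResult",
    "relevance_profile",
    "fsbrr_select",
    "select_from_table",
    "make_fsbrr_selector",
    "sweep",
    "selection_to_dict",
    "write_selection_json",
    "write_feature_list",
]

RULE_IRRELEVANT = "irrelevant"
RULE_REDUNDANCY_1 = "redundancy_rule_1"
RULE_REDUNDANCY_2 = "redundancy_rule_2"

# Recommended parameter ranges; violations warn but do not error.
DELTA_RANGE = (0.05, 0.13)
ALPHA_RANGE = (0.60, 0.66)


@dataclass(frozen=True)
class FSBRRConfig:
    """Selector parameters.

    tau
        Irrelevance threshold on R_i,c (default 0: keep even weakly
        relevant features absent prior knowledge).
    delta
        Gap width within which rule 1 applies (default 0.08).
    alpha
        Upper gap bound for rule 2 (default 0.64; strict ``<``).
    binning
        Discretization applied to continuous columns before any entropy.
    seed
        For downstream stochastic consumers; selection itself is
        deterministic.
    r_bar_scope
        ``"retained"`` (default) averages R_i,c over the tau-survivors;
        ``"all"`` averages over every input feature.  Identical when tau=0.
    """

    tau: float = 0.0
    delta: float = 0.08
    alpha: float = 0.64
    binning: BinningSpec = field(default_factory=BinningSpec)
    seed: int = 0
    r_bar_scope: str = "retained"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.r_bar_scope not in ("retained", "all"):
            raise ValueError("r_bar_scope must be 'retained' or 'all'")
        if not (DELTA_RANGE[0] <= self.delta <= DELTA_RANGE[1]):
            warnings.warn(
                f"delta={self.delta} outside recommended range "
                f"[{DELTA_RANGE[0]}, {DELTA_RANGE[1]}]",
                stacklevel=2,
            )
        if not (ALPHA_RANGE[0] <= self.alpha <= ALPHA_RANGE[1]):
            warnings.warn(
                f"alpha={self.alpha} outside recommended range "
                f"[{ALPHA_RANGE[0]}, {ALPHA_RANGE[1]}]",
                stacklevel=2,
            )
        if not self.delta < self.alpha:
            warnings.warn(
                f"delta={self.delta} not smaller than alpha={self.alpha}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RemovalRecord:
    """One removal event: which rule fired, on which pair, at which scores."""

    removed: str
    rule: str
    r_removed_class: float
    pivot: Optional[str] = None
    r_pivot_class: Optional[float] = None
    r_pair: Optional[float] = None


@dataclass
class RelevanceProfile:
    """Per-feature class relevance after the tau filter."""

    scores: dict[str, float]  # retained feature id -> R_i,c
    r_max: float
    r_bar: float
    dropped: list[RemovalRecord]

    def __post_init__(self) -> None:
        assert self.r_bar <= self.r_max + 1e-12


@dataclass
class SelectionResult:
    """Outcome of one selector run.

    ``selected`` is ordered by descending R_i,c; ``pair_evaluations``
    counts the R_i,j computations actually performed, exposing the
    linear-to-quadratic complexity range of the redundancy pass.
    """

    selected: list[str]
    scores: dict[str, float]
    removal_log: list[RemovalRecord]
    pair_evaluations: int
    r_max: float
    r_bar: float
    config: FSBRRConfig


def relevance_profile(table: DiscretizedTable, config: FSBRRConfig) -> RelevanceProfile:
    """Compute R_i,c for every feature and apply the tau irrelevance filter.

    Raises if the class has fewer than two categories or if no feature
    survives the filter.
    """
    if table.n_features < 1:
        raise ValueError("table has no features")
    if table.class_codes.cardinality < 2:
        raise ValueError("class vector must contain at least 2 categories")
    scores: dict[str, float] = {}
    dropped: list[RemovalRecord] = []
    all_scores: list[float] = []
    for fid, col in zip(table.feature_ids, table.features):
        r = normalized_relevance(col, table.class_codes)
        all_scores.append(r)
        if col.cardinality == 1:
            warnings.warn(
                f"feature {fid!r} is constant (R=0); consider tau > 0",
                stacklevel=2,
            )
        if r >= config.tau:
            scores[fid] = r
        else:
            dropped.append(
                RemovalRecord(removed=fid, rule=RULE_IRRELEVANT, r_removed_class=r)
            )
    if not scores:
        raise ValueError("empty after irrelevance filter")
    retained = list(scores.values())
    r_bar_pool = all_scores if config.r_bar_scope == "all" else retained
    profile = RelevanceProfile(
        scores=scores,
        r_max=max(retained),
        r_bar=float(np.mean(r_bar_pool)),
        dropped=dropped,
    )
    logger.info(
        "relevance filter (tau=%g): kept %d of %d features, r_max=%.4f r_bar=%.4f",
        config.tau,
        len(scores),
        table.n_features,
        profile.r_max,
        profile.r_bar,
    )
    return profile


def fsbrr_select(table: DiscretizedTable, config: FSBRRConfig) -> SelectionResult:
    """Run the full selector on a discretized table.  Deterministic."""
    profile = relevance_profile(table, config)
    id_to_idx = {fid: k for k, fid in enumerate(table.feature_ids)}
    # Descending relevance; ties broken by ascending original column index.
    order = sorted(profile.scores, key=lambda f: (-profile.scores[f], id_to_idx[f]))
    alive = {fid: True for fid in order}
    removal_log = list(profile.dropped)
    pair_evaluations = 0
    r_bar = profile.r_bar

    for a, fi in enumerate(order):
        if not alive[fi]:
            continue
        r_ic = profile.scores[fi]
        col_i = table.features[id_to_idx[fi]]
        for fj in order[a + 1 :]:
            if not alive[fj]:
                continue
            r_jc = profile.scores[fj]
            r_ij = normalized_relevance(col_i, table.features[id_to_idx[fj]])
            pair_evaluations += 1
            gap = r_ic - r_jc
            if gap <= config.delta and r_ij >= r_ic:
                rule = RULE_REDUNDANCY_1
            elif gap > config.delta and gap < config.alpha and r_ij > (r_bar + r_jc) / 2:
                rule = RULE_REDUNDANCY_2
            else:
                continue
            alive[fj] = False
            removal_log.append(
                RemovalRecord(
                    removed=fj,
                    rule=rule,
                    r_removed_class=r_jc,
                    pivot=fi,
                    r_pivot_class=r_ic,
                    r_pair=r_ij,
                )
            )

    selected = [fid for fid in order if alive[fid]]
    logger.info(
        "selected %d of %d features (delta=%g alpha=%g, %d pair evaluations)",
        len(selected),
        table.n_features,
        config.delta,
        config.alpha,
        pair_evaluations,
    )
    return SelectionResult(
        selected=selected,
        scores={fid: profile.scores[fid] for fid in selected},
        removal_log=removal_log,
        pair_evaluations=pair_evaluations,
        r_max=profile.r_max,
        r_bar=r_bar,
        config=config,
    )


def select_from_table(table, config: FSBRRConfig | None = None) -> SelectionResult:
    """Discretize a raw FeatureTable per the config's binning, then select."""
    config = config or FSBRRConfig()
    return fsbrr_select(discretize_table(table, config.binning), config)


def make_fsbrr_selector(config: FSBRRConfig | None = None) -> Callable:
    """Return a ``FeatureTable -> list[str]`` closure for the CV harness."""
    config = config or FSBRRConfig()

    def _selector(table) -> list[str]:
        return select_from_table(table, config).selected

    return _selector


def sweep(
    table: DiscretizedTable,
    delta_grid,
    alpha_grid,
    config: FSBRRConfig,
    evaluator: Optional[Callable[[list[str]], float]] = None,
):
    """Run the selector over a (delta, alpha) grid.

    One of the grids is typically a singleton (delta swept at fixed alpha
    or vice versa).  ``evaluator`` maps a selected-id list to a performance
    number (e.g. a cross-validated composite score); when omitted the
    performance column is NaN.  Returns a pandas DataFrame with columns
    ``delta, alpha, n_selected, performance``.
    """
    import pandas as pd

    delta_grid = list(delta_grid)
    alpha_grid = list(alpha_grid)
    if not delta_grid or not alpha_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # grid points stray outside ranges
        for delta, alpha in product(delta_grid, alpha_grid):
            cfg = FSBRRConfig(
                tau=config.tau,
                delta=delta,
                alpha=alpha,
                binning=config.binning,
                seed=config.seed,
                r_bar_scope=config.r_bar_scope,
            )
            result = fsbrr_select(table, cfg)
            perf = float("nan") if evaluator is None else evaluator(result.selected)
            rows.append(
                {
                    "delta": delta,
                    "alpha": alpha,
                    "n_selected": len(result.selected),
                    "performance": perf,
                }
            )
    return pd.DataFrame(rows)


def selection_to_dict(result: SelectionResult) -> dict:
    """JSON-serializable view of a SelectionResult (config echoed)."""
    cfg = asdict(result.config)
    cfg["binning"] = asdict(result.config.binning)
    return {
        "selected": result.selected,
        "scores": result.scores,
        "removal_log": [asdict(r) for r in result.removal_log],
        "pair_evaluations": result.pair_evaluations,
        "r_max": result.r_max,
        "r_bar": result.r_bar,
        "config": cfg,
    }


def write_selection_json(result: SelectionResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(selection_to_dict(result), fh, indent=2)
        fh.write("\n")


def write_feature_list(result: SelectionResult, path: str | Path) -> None:
    """Plain-text output, one surviving feature id per line."""
    Path(path).write_text("".join(f"{fid}\n" for fid in result.selected))
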