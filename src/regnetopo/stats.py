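"""Inference statistics for gene-set topology.

This module implements the bespoke statistics of the analysis:

* the **Target Compact Rate (TCR)** of a miRNA set,

      TCR = (<N_targ>/<K_out> - 1/N_mir) / (1 - 1/N_mir)

  where ``N_mir`` is the number of miRNAs in the set, ``<K_out>`` the
  mean out-degree and ``<N_targ>`` the number of *distinct* targets of
  the whole set divided by ``N_mir``.  TCR is 1 when every out-edge
  points at a target no other set member regulates (fully disjoint
  target sets) and 0 when all members regulate one identical target
  set;

* the **random-set resampling test** for topological bias of a small
  gene set against a large background: the small set's mean centrality
  is ranked within the means of resampled background sets of the same
  size, giving empirical one-sided P-values;

* **Fisher exact tests** for neighbor-composition enrichment and for
  association between gene classes.

Empirical P-values use the add-one estimator (r + 1)/(R + 1) with ties
counted in both tails, so P >= 1/(R + 1) always and a finite resample
can never report P = 0.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .network import (
    GeneClassPartition,
    NodeType,
    RegulatoryNetwork,
)

__all__ = [
    "Direction",
    "TCRResult",
    "SetComparisonResult",
    "EnrichmentResult",
    "tcr",
    "connected_tf_count",
    "compare_sets",
    "neighbor_enrichment",
    "class_association",
]

#: Largest number of enumerated null sets accepted by the exhaustive method.
_MAX_EXHAUSTIVE = 200_000


class Direction(str, enum.Enum):
    HIGHER = "HIGHER"
    LOWER = "LOWER"
    NONE = "NONE"


# -- Target Compact Rate -------------------------------------------------


@dataclass(frozen=True)
class TCRResult:
    """Components and value of the Target Compact Rate for a miRNA set."""

    n_mir: int
    mean_out_degree: float
    mean_target_number: float
    tcr: float


def tcr(net: RegulatoryNetwork, mirna_set) -> TCRResult:
    """Target Compact Rate of a miRNA set within a network.

    Requires at least two miRNAs (the denominator 1 - 1/N_mir vanishes
    otherwise) and every member to have out-degree >= 1.
    """
    ids = sorted(mirna_set)
    n_mir = len(ids)
    if n_mir < 2:
        raise ValueError(f"TCR needs at least 2 miRNAs, got {n_mir}")
    total_out = 0
    union_targets: set[str] = set()
    for mid in ids:
        if mid not in net:
            raise KeyError(f"unknown node {mid!r}")
        node = net.node(mid)
        if node.node_type is not NodeType.MIRNA:
            raise ValueError(f"node {mid!r} is not a miRNA")
        targets = net.out_neighbors(mid)
        if not targets:
            raise ValueError(f"miRNA {mid!r} has out-degree 0")
        total_out += len(targets)
        union_targets |= targets
    mean_out = total_out / n_mir
    mean_targ = len(union_targets) / n_mir
    value = (mean_targ / mean_out - 1.0 / n_mir) / (1.0 - 1.0 / n_mir)
    return TCRResult(
        n_mir=n_mir,
        mean_out_degree=mean_out,
        mean_target_number=mean_targ,
        tcr=value,
    )


def connected_tf_count(net: RegulatoryNetwork, mirna_set) -> float:
    """Mean number of distinct TFs neighboring each miRNA in the set.

    A TF counts once per miRNA whether it regulates the miRNA, is
    regulated by it, or both.
    """
    ids = sorted(mirna_set)
    if not ids:
        raise ValueError("empty miRNA set")
    counts = []
    for mid in ids:
        node = net.node(mid)
        if node.node_type is not NodeType.MIRNA:
            raise ValueError(f"node {mid!r} is not a miRNA")
        tf_neighbors = {
            nid
            for nid in net.neighbors(mid)
            if net.node(nid).node_type is NodeType.TF
        }
        counts.append(len(tf_neighbors))
    return float(np.mean(counts))


# -- random-set resampling test ------------------------------------------


@dataclass
class SetComparisonResult:
    """Outcome of one small-set-vs-background centrality comparison."""

    parameter: str
    observed_mean: float
    null_means: np.ndarray
    p_greater: float
    p_less: float
    significant_direction: Direction
    alpha: float
    n_resamples: int
    seed: int | None = None

    def recompute_p(self) -> tuple[float, float]:
        """Re-derive both P-values from the stored null means."""
        r = len(self.null_means)
        p_g = (1 + int(np.sum(self.null_means >= self.observed_mean))) / (
            r + 1
        )
        p_l = (1 + int(np.sum(self.null_means <= self.observed_mean))) / (
            r + 1
        )
        return p_g, p_l


def _direction(p_greater: float, p_less: float, alpha: float) -> Direction:
    if p_greater < alpha and p_less < alpha:
        # Only possible under extreme tying; report no direction.
        return Direction.NONE
    if p_greater < alpha:
        return Direction.HIGHER
    if p_less < alpha:
        return Direction.LOWER
    return Direction.NONE


def compare_sets(
    profile: pd.DataFrame,
    small_set,
    background,
    parameter: str,
    n_resamples: int = 2000,
    alpha: float = 0.10,
    seed: int | np.random.Generator | None = None,
    method: str = "resample",
) -> SetComparisonResult:
    """Empirical test of topological bias of ``small_set`` vs background.

    The observed statistic is the mean of ``parameter`` over the small
    set.  The null is built by drawing ``n_resamples`` random sets of
    the same size from the background (uniform, without replacement
    within each set, independent across sets) and taking their means.
    ``p_greater`` is the add-one tail proportion of null means >= the
    observed mean; ``p_less`` symmetrically.  A one-sided P below
    ``alpha`` (default 0.10) declares a significant direction.

    ``method="exhaustive"`` replaces resampling by full enumeration of
    every background subset of the small-set size (only feasible for
    tiny problems); the same add-one convention applies with the number
    of enumerated sets in place of ``n_resamples``.
    """
    small = sorted(small_set)
    bg = sorted(background)
    if not small or not bg:
        raise ValueError("small_set and background must be nonempty")
    if set(small) & set(bg):
        raise ValueError("small_set and background must be disjoint")
    if len(bg) < len(small):
        raise ValueError(
            f"background ({len(bg)}) smaller than small set ({len(small)})"
        )
    if parameter not in profile.columns:
        raise KeyError(f"parameter {parameter!r} not in profile")
    small_vals = profile.loc[small, parameter].to_numpy(dtype=float)
    bg_vals = profile.loc[bg, parameter].to_numpy(dtype=float)
    if not (np.isfinite(small_vals).all() and np.isfinite(bg_vals).all()):
        raise ValueError(f"non-finite {parameter!r} values")
    observed = float(small_vals.mean())
    k = len(small)

    if method == "exhaustive":
        n_sets = math.comb(len(bg), k)
        if n_sets > _MAX_EXHAUSTIVE:
            raise ValueError(
                f"exhaustive enumeration infeasible: {n_sets} subsets"
            )
        null_means = np.array(
            [
                float(np.mean(combo))
                for combo in itertools.combinations(bg_vals, k)
            ]
        )
        seed_out = None
    elif method == "resample":
        if isinstance(seed, np.random.Generator):
            rng = seed
            seed_out = None
        else:
            rng = np.random.default_rng(seed)
            seed_out = seed
        # Without-replacement sample per row: k smallest of random keys.
        keys = rng.random((n_resamples, len(bg)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_means = bg_vals[idx].mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")

    r = len(null_means)
    p_greater = (1 + int(np.sum(null_means >= observed))) / (r + 1)
    p_less = (1 + int(np.sum(null_means <= observed))) / (r + 1)
    return SetComparisonResult(
        parameter=parameter,
        observed_mean=observed,
        null_means=null_means,
        p_greater=p_greater,
        p_less=p_less,
        significant_direction=_direction(p_greater, p_less, alpha),
        alpha=alpha,
        n_resamples=r,
        seed=seed_out,
    )


# -- Fisher exact tests --------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 contingency table with Fisher exact test outcome.

    ``odds_ratio`` is the sample (cross-product) odds ratio: infinity
    when only the off-diagonal of one row is empty, NaN when a margin is
    degenerate (``degenerate=True``, P fixed at 1).
    """

    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    degenerate: bool = False


def _fisher(table: np.ndarray, alternative: str = "two-sided") -> EnrichmentResult:
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("contingency table must be 2x2 nonnegative")
    a, b = table[0]
    c, d = table[1]
    contingency = ((int(a), int(b)), (int(c), int(d)))
    row_degen = (a + b == 0) or (c + d == 0)
    col_degen = (a + c == 0) or (b + d == 0)
    if row_degen or col_degen:
        return EnrichmentResult(
            contingency=contingency,
            odds_ratio=math.nan,
            p_value=1.0,
            degenerate=True,
        )
    odds, p = sp_stats.fisher_exact(table, alternative=alternative)
    return EnrichmentResult(
        contingency=contingency, odds_ratio=float(odds), p_value=float(p)
    )


def neighbor_enrichment(
    net: RegulatoryNetwork,
    focal_set,
    neighbor_class: NodeType,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher exact test: is ``neighbor_class`` over-represented among the
    neighbors of ``focal_set``?

    Every non-focal node is cross-classified as (neighbor of at least
    one focal node vs. not) x (of ``neighbor_class`` vs. not).  The test
    is two-sided by default.
    """
    focal = set(focal_set)
    if not focal:
        raise ValueError("focal_set must be nonempty")
    for fid in focal:
        if fid not in net:
            raise KeyError(f"unknown node {fid!r}")
    neighbor_class = NodeType(neighbor_class)
    neighbor_ids: set[str] = set()
    for fid in focal:
        neighbor_ids |= net.neighbors(fid)
    neighbor_ids -= focal
    table = np.zeros((2, 2), dtype=int)
    for nid in net.node_ids:
        if nid in focal:
            continue
        is_neighbor = nid in neighbor_ids
        in_class = net.node(nid).node_type is neighbor_class
        table[0 if is_neighbor else 1, 0 if in_class else 1] += 1
    return _fisher(table, alternative=alternative)


def class_association(
    partition_a: GeneClassPartition,
    partition_b: GeneClassPartition,
    universe,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher exact test of association between two class memberships
    over a common universe of node ids."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    set_a = set(partition_a.member_ids)
    set_b = set(partition_b.member_ids)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("partitions must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - len(set_a | set_b)
    return _fisher(
        np.array([[a, b], [c, d]], dtype=int), alternative=alternative
    )
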