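"""Differential hub co-expression scanning between two conditions.

For each network hub (node with more than 4 partners by default) the
disruption statistic is

    S = (1/|P'|) * sum over usable partners p of | r(hub, p | A) - r(hub, p | B) |

where r is the Pearson correlation across samples of condition A or B and P'
excludes partners missing from the matrix or with zero variance in either
condition.  Significance comes from a permutation null: condition labels are
reshuffled across samples preserving group sizes, and

    p = (1 + #{S_perm >= S_obs}) / (1 + n_perm).

The consensus scan repeats the test on stratified two-thirds subsamples
(ceiling rounding per condition, e.g. 14 tumors + 8 normals from 21 + 12) and
calls a hub disrupted only when it is significant in every run.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np

from .containers import ConsensusResult, ExpressionMatrix, HubResult

__all__ = [
    "extract_skeleton",
    "identify_hubs",
    "hub_statistic",
    "permutation_pvalue",
    "consensus_scan",
    "cross_species_confirm",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# network operations


def extract_skeleton(net: nx.Graph, retain_fraction: float = 0.2) -> nx.Graph:
    """Keep the top ceil(retain_fraction * |E|) edges by edge betweenness.

    Degree-0 nodes are removed afterwards, so ``retain_fraction = 1`` returns
    the input minus pre-existing singletons.  Ties in betweenness are broken
    by sorted edge name for determinism.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    if net.number_of_edges() == 0:
        raise ValueError("cannot extract a skeleton from a graph with no edges")
    n_keep = math.ceil(retain_fraction * net.number_of_edges())
    ebc = nx.edge_betweenness_centrality(net)
    ranked = sorted(ebc.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
    kept = [e for e, _ in ranked[:n_keep]]
    skel = nx.Graph()
    skel.add_nodes_from(net.nodes)
    skel.add_edges_from(kept)
    skel.remove_nodes_from([n for n, d in skel.degree() if d == 0])
    return skel


def identify_hubs(net: nx.Graph, min_partners: int = 5) -> set[str]:
    """Nodes with at least ``min_partners`` neighbours (default: >4 partners)."""
    return {n for n, d in net.degree() if d >= min_partners}


# ---------------------------------------------------------------------------
# correlation-difference statistic


def _usable_partners(
    hub: str, partners: list[str], expr: ExpressionMatrix
) -> list[str]:
    """Partners present in the matrix with nonzero variance in both conditions."""
    lv = expr.levels
    usable = []
    present = set(expr.values.index)
    for p in partners:
        if p not in present or p == hub:
            continue
        x = expr.values.loc[p]
        if all(x[expr.samples_of(c)].std() > 0 for c in lv):
            usable.append(p)
    return usable


def _masked_correlations(
    hub_row: np.ndarray, partner_rows: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """Pearson r of hub vs each partner within each boolean column mask.

    hub_row: (n,); partner_rows: (k, n); masks: (m, n) boolean.
    Returns (m, k).  Vectorised as mask matmuls so a thousand permutations
    cost a handful of BLAS calls.  Zero-variance subsets yield r = 0.
    """
    masks = masks.astype(float)
    n = masks.sum(axis=1)  # (m,)
    sum_h = masks @ hub_row
    sum_h2 = masks @ (hub_row * hub_row)
    sums_p = masks @ partner_rows.T          # (m, k)
    sums_p2 = masks @ (partner_rows * partner_rows).T
    cross = masks @ (partner_rows * hub_row).T

    mean_h = sum_h / n
    var_h = sum_h2 / n - mean_h**2
    mean_p = sums_p / n[:, None]
    var_p = sums_p2 / n[:, None] - mean_p**2
    cov = cross / n[:, None] - mean_p * mean_h[:, None]
    denom = np.sqrt(np.clip(var_h[:, None] * var_p, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > _EPS, cov / np.where(denom > _EPS, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def _scores_for_masks(
    hub_row: np.ndarray, partner_rows: np.ndarray, masks_a: np.ndarray
) -> np.ndarray:
    """S for each split: mean over partners of |r_A - r_B| (B = complement)."""
    r_a = _masked_correlations(hub_row, partner_rows, masks_a)
    r_b = _masked_correlations(hub_row, partner_rows, ~masks_a)
    return np.abs(r_a - r_b).mean(axis=1)


def hub_statistic(
    hub: str, partners: list[str], expr: ExpressionMatrix
) -> HubResult:
    """Observed disruption score for one hub (no p-value).

    Partners missing from the matrix or with zero variance in either
    condition are dropped; with no usable partner the result carries
    ``score = nan`` and is excluded downstream rather than silently zero.
    """
    usable = _usable_partners(hub, partners, expr)
    if hub not in set(expr.values.index) or not usable:
        return HubResult(hub_id=hub, partner_ids=[], score=float("nan"),
                         n_partners_used=0)
    lv = expr.levels
    cond = expr.condition.to_numpy()
    mask_a = (cond == lv[0])[None, :]
    hub_row = expr.values.loc[hub].to_numpy(dtype=float)
    partner_rows = expr.values.loc[usable].to_numpy(dtype=float)
    score = float(_scores_for_masks(hub_row, partner_rows, mask_a)[0])
    return HubResult(hub_id=hub, partner_ids=usable, score=score,
                     n_partners_used=len(usable))


def _permutation_masks(
    rng: np.random.Generator, n_samples: int, n_a: int, n_perm: int
) -> np.ndarray:
    """n_perm boolean rows, each a random size-n_a subset marked True."""
    order = rng.random((n_perm, n_samples)).argsort(axis=1)
    masks = np.zeros((n_perm, n_samples), dtype=bool)
    rows = np.repeat(np.arange(n_perm), n_a)
    masks[rows, order[:, :n_a].ravel()] = True
    return masks


def permutation_pvalue(
    hub: str,
    partners: list[str],
    expr: ExpressionMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> HubResult:
    """Permutation p-value for one hub's disruption score.

    Condition labels are permuted across all samples preserving group sizes;
    the add-one-smoothed p is (1 + #{S_perm >= S_obs}) / (1 + n_perm), hence
    always > 0.
    """
    result = hub_statistic(hub, partners, expr)
    if not result.usable:
        return result
    rng = np.random.default_rng(seed)
    lv = expr.levels
    cond = expr.condition.to_numpy()
    # S is symmetric under mask complement, so drawing subsets of the smaller
    # group's size samples the same null and makes p independent of which
    # condition is called "A"
    n_draw = min(int((cond == lv[0]).sum()), int((cond == lv[1]).sum()))
    masks = _permutation_masks(rng, len(cond), n_draw, n_perm)
    hub_row = expr.values.loc[hub].to_numpy(dtype=float)
    partner_rows = expr.values.loc[result.partner_ids].to_numpy(dtype=float)
    s_perm = _scores_for_masks(hub_row, partner_rows, masks)
    result.p_value = float((1 + np.sum(s_perm >= result.score)) / (1 + n_perm))
    return result


# ---------------------------------------------------------------------------
# consensus scan


def _scan_once(
    expr: ExpressionMatrix,
    net: nx.Graph,
    hubs: list[str],
    n_perm: int,
    rng: np.random.Generator,
) -> dict[str, HubResult]:
    """Permutation p for every hub, sharing one permutation mask set."""
    lv = expr.levels
    cond = expr.condition.to_numpy()
    n_draw = min(int((cond == lv[0]).sum()), int((cond == lv[1]).sum()))
    masks = _permutation_masks(rng, len(cond), n_draw, n_perm)
    results: dict[str, HubResult] = {}
    for hub in hubs:
        res = hub_statistic(hub, list(net.neighbors(hub)), expr)
        if res.usable:
            hub_row = expr.values.loc[hub].to_numpy(dtype=float)
            partner_rows = expr.values.loc[res.partner_ids].to_numpy(dtype=float)
            s_perm = _scores_for_masks(hub_row, partner_rows, masks)
            res.p_value = float((1 + np.sum(s_perm >= res.score)) / (1 + n_perm))
        results[hub] = res
    return results


def consensus_scan(
    expr: ExpressionMatrix,
    net: nx.Graph,
    n_runs: int = 3,
    subsample_fraction: float = 2 / 3,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_partners: int = 5,
) -> ConsensusResult:
    """Subsample-consensus hub scan.

    Each run draws a stratified subsample (ceil(fraction * n) per condition,
    so 21 tumors + 12 normals give 14 + 8 at 2/3), computes every hub's
    permutation p on it, and records hubs with p <= alpha; the disrupted set
    is the intersection over runs.
    """
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    hubs = sorted(identify_hubs(net, min_partners=min_partners))
    lv = expr.levels
    per_level = {c: expr.samples_of(c) for c in lv}
    take = {c: math.ceil(subsample_fraction * len(s)) for c, s in per_level.items()}
    if any(t < 3 for t in take.values()):
        raise ValueError("subsample leaves < 3 samples in a condition")

    ss = np.random.SeedSequence(seed)
    run_rngs = [np.random.default_rng(child) for child in ss.spawn(n_runs)]
    runs: list[set[str]] = []
    per_run_results: list[dict[str, HubResult]] = []
    for rng in run_rngs:
        chosen: list[str] = []
        for c in lv:
            pool = per_level[c]
            idx = rng.choice(len(pool), size=take[c], replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        sub = expr.subset_samples(chosen)
        results = _scan_once(sub, net, hubs, n_perm, rng)
        sig = {h for h, r in results.items() if r.usable and r.p_value <= alpha}
        runs.append(sig)
        per_run_results.append(results)
    return ConsensusResult(runs=runs, alpha=alpha,
                           subsample_fraction=subsample_fraction,
                           per_run_results=per_run_results)


def cross_species_confirm(
    result_a: ConsensusResult,
    result_b: ConsensusResult,
    ortholog_map: dict[str, str],
) -> set[str]:
    """Hubs disrupted in species A whose ortholog is disrupted in species B.

    ``ortholog_map`` maps species-A ids to species-B ids and must already be
    one-to-one; A hubs without a mapping are skipped with a log message.
    """
    hits_b = result_b.disrupted_hubs
    confirmed = set()
    for hub in result_a.disrupted_hubs:
        ortholog = ortholog_map.get(hub)
        if ortholog is None:
            logger.info("hub %s has no ortholog mapping; skipped", hub)
            continue
        if ortholog in hits_b:
            confirmed.add(hub)
    return confirmed
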