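"""Synthetic-data generators with the statistical structure each stage assumes.

Three generators mirror the three analysis stages:

* :func:`gen_expression` - hub-structured co-expression matrices for two
  conditions (tumor / normal), where a chosen subset of hubs loses its
  hub-partner correlation in tumors.  One-factor blocks: each partner is the
  hub's latent signal mixed with independent noise so the generating Pearson
  correlation is exactly the requested ``r``.
* :func:`gen_screen` - pooled shRNA counts as a Poisson-gamma (negative
  binomial) hierarchy with a shared per-shRNA abundance between T0 and tumor
  replicates, injected gene depletion, and optional multiplicative outliers.
* :func:`gen_doseresponse` - median-effect dose-response tables for one to
  three drugs; combination rows solve the Loewe sum
  ``sum_i D_i / Dx_i(fa) = 1/alpha`` so the ground-truth combination index is
  analytically ``1/alpha``.

Every generator is a pure function of its spec, including the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ExpressionMatrix, ScreenCounts

__all__ = [
    "SimExpressionSpec",
    "SimScreenSpec",
    "SimDoseSpec",
    "gen_expression",
    "gen_screen",
    "gen_doseresponse",
    "combine_screens",
]


# ---------------------------------------------------------------------------
# expression


@dataclass
class SimExpressionSpec:
    """Design of a two-condition hub/partner co-expression dataset.

    ``r_normal`` is the hub-partner Pearson correlation in normal samples (and
    in tumor samples for non-disrupted hubs); disrupted hubs switch to
    ``r_tumor_disrupted`` in tumors.  ``noise_sd`` scales the per-gene
    log-intensity spread and does not affect correlations.  Defaults emulate a
    21-tumor / 12-normal transcriptome design.
    """

    n_hubs: int = 100
    partners_per_hub: int = 5
    n_tumor: int = 21
    n_normal: int = 12
    r_normal: float = 0.9
    r_tumor_disrupted: float = -0.9
    disrupted_hub_ids: frozenset = frozenset()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ValueError("need >= 3 samples per condition")
        for r in (self.r_normal, self.r_tumor_disrupted):
            if abs(r) > 1:
                raise ValueError(f"correlation {r} outside [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (zero gives a degenerate, "
                             "variance-free matrix)")
        self.disrupted_hub_ids = frozenset(self._hub_id(h) for h in self.disrupted_hub_ids)
        known = {self._hub_id(i) for i in range(self.n_hubs)}
        unknown = self.disrupted_hub_ids - known
        if unknown:
            raise ValueError(f"disrupted_hub_ids not among generated hubs: {sorted(unknown)}")

    @staticmethod
    def _hub_id(h) -> str:
        return f"hub_{h:04d}" if isinstance(h, (int, np.integer)) else str(h)


def _correlated_partner(rng: np.random.Generator, hub_z: np.ndarray, r: float) -> np.ndarray:
    eps = rng.standard_normal(hub_z.shape)
    return r * hub_z + np.sqrt(max(1.0 - r * r, 0.0)) * eps


def gen_expression(
    spec: SimExpressionSpec,
) -> tuple[ExpressionMatrix, nx.Graph, set[str]]:
    """Generate (expression matrix, hub-partner network, disrupted-hub truth).

    Samples are labelled ``tumor`` / ``normal``; hub ``hub_0007``'s partners
    are ``hub_0007_p0`` ... and are its direct neighbours in the network.
    """
    rng = np.random.default_rng(spec.seed)
    n_t, n_n = spec.n_tumor, spec.n_normal
    sample_ids = [f"T{i:03d}" for i in range(n_t)] + [f"N{i:03d}" for i in range(n_n)]
    condition = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=sample_ids)

    net = nx.Graph()
    rows: dict[str, np.ndarray] = {}
    for i in range(spec.n_hubs):
        hub = f"hub_{i:04d}"
        disrupted = hub in spec.disrupted_hub_ids
        r_tum = spec.r_tumor_disrupted if disrupted else spec.r_normal
        hub_z = rng.standard_normal(n_t + n_n)
        baseline_hub = rng.uniform(6.0, 12.0)
        rows[hub] = baseline_hub + spec.noise_sd * hub_z
        for j in range(spec.partners_per_hub):
            partner = f"{hub}_p{j}"
            z = np.empty(n_t + n_n)
            z[:n_t] = _correlated_partner(rng, hub_z[:n_t], r_tum)
            z[n_t:] = _correlated_partner(rng, hub_z[n_t:], spec.r_normal)
            rows[partner] = rng.uniform(6.0, 12.0) + spec.noise_sd * z
            net.add_edge(hub, partner)

    values = pd.DataFrame(rows, index=sample_ids).T
    expr = ExpressionMatrix(values=values, condition=condition)
    return expr, net, set(spec.disrupted_hub_ids)


# ---------------------------------------------------------------------------
# pooled screen


@dataclass
class SimScreenSpec:
    """Design of a pooled dropout screen: one T0 pool and n tumor replicates.

    Counts follow a Poisson-gamma hierarchy: each shRNA draws a latent
    abundance lambda ~ Gamma(shape=dispersion, mean=mean_t0_count) shared by
    all samples, so T0 counts are marginally negative binomial and tumor/T0
    ratios are tight around the injected fold change.  Six tumor replicates
    per line mirror the in vivo design.
    """

    n_genes: int = 100
    shrnas_per_gene: int = 4
    n_tumor_reps: int = 6
    mean_t0_count: float = 1000.0
    dispersion: float = 10.0
    depleted_gene_ids: frozenset = frozenset()
    depletion_factor: float = 0.1
    outlier_rate: float = 0.0
    outlier_factor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor_reps < 4:
            raise ValueError("need >= 4 tumor replicates")
        if not 0 < self.depletion_factor < 1:
            raise ValueError("depletion_factor must be in (0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.mean_t0_count <= 0 or self.dispersion <= 0:
            raise ValueError("mean_t0_count and dispersion must be positive")
        self.depleted_gene_ids = frozenset(self._gene_id(g) for g in self.depleted_gene_ids)
        known = {self._gene_id(i) for i in range(self.n_genes)}
        unknown = self.depleted_gene_ids - known
        if unknown:
            raise ValueError(f"depleted_gene_ids not among generated genes: {sorted(unknown)}")

    @staticmethod
    def _gene_id(g) -> str:
        return f"gene_{g:04d}" if isinstance(g, (int, np.integer)) else str(g)


def gen_screen(
    spec: SimScreenSpec, cell_line: str = "LINE1"
) -> tuple[ScreenCounts, set[str], list[tuple[str, str]]]:
    """Generate (screen counts, depleted-gene truth, injected outlier coords).

    Outlier coordinates are (shRNA id, tumor sample id) pairs whose counts
    were multiplied by ``outlier_factor``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene_{i:04d}" for i in range(spec.n_genes)]
    shrnas = [f"sh_{g}_{k}" for g in genes for k in range(spec.shrnas_per_gene)]
    gene_of = pd.Series(
        [g for g in genes for _ in range(spec.shrnas_per_gene)], index=shrnas
    )
    n_sh = len(shrnas)

    lam = rng.gamma(shape=spec.dispersion,
                    scale=spec.mean_t0_count / spec.dispersion, size=n_sh)
    t0 = rng.poisson(lam).astype(float)

    fold = np.where(gene_of.isin(spec.depleted_gene_ids).to_numpy(),
                    spec.depletion_factor, 1.0)
    tumor = rng.poisson(lam[:, None] * fold[:, None],
                        size=(n_sh, spec.n_tumor_reps)).astype(float)

    tumor_ids = [f"{cell_line}_tumor_{k + 1}" for k in range(spec.n_tumor_reps)]
    outliers: list[tuple[str, str]] = []
    if spec.outlier_rate > 0:
        hit = rng.random((n_sh, spec.n_tumor_reps)) < spec.outlier_rate
        tumor[hit] *= spec.outlier_factor
        for i, j in zip(*np.nonzero(hit)):
            outliers.append((shrnas[i], tumor_ids[j]))

    t0_id = f"{cell_line}_T0"
    counts = pd.DataFrame(
        np.column_stack([t0, tumor]), index=shrnas, columns=[t0_id] + tumor_ids
    )
    samples = pd.DataFrame(
        {
            "cell_line": cell_line,
            "timepoint": ["T0"] + ["tumor"] * spec.n_tumor_reps,
            "replicate": list(range(spec.n_tumor_reps + 1)),
        },
        index=[t0_id] + tumor_ids,
    )
    sc = ScreenCounts(counts=counts, gene_of=gene_of, samples=samples)
    return sc, set(spec.depleted_gene_ids), outliers


def combine_screens(parts: list[ScreenCounts]) -> ScreenCounts:
    """Stack per-cell-line screens (same shRNA library) into one table."""
    first = parts[0]
    for p in parts[1:]:
        if list(p.counts.index) != list(first.counts.index):
            raise ValueError("screens must share the same shRNA library")
    counts = pd.concat([p.counts for p in parts], axis=1)
    samples = pd.concat([p.samples for p in parts], axis=0)
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids across screens")
    return ScreenCounts(counts=counts, gene_of=first.gene_of.copy(),
                        samples=samples)


# ---------------------------------------------------------------------------
# dose response


@dataclass
class SimDoseSpec:
    """Design of median-effect dose-response and constant-ratio combo data.

    ``m_true`` / ``dm_true`` may be scalars (shared by all drugs) or
    per-drug sequences.  ``synergy_alpha`` scales the Loewe sum: combo rows
    satisfy ``sum_i D_i/Dx_i(fa) = 1/alpha``, so alpha > 1 means synergy and
    the ground-truth CI is 1/alpha.  ``ratio`` sets each further drug's dose
    relative to drug 1 in constant-ratio combos.
    """

    m_true: float | tuple = 1.0
    dm_true: float | tuple = 10.0
    doses: tuple = (1.0, 3.0, 10.0, 30.0, 100.0)
    cv_noise: float = 0.0
    synergy_alpha: float = 1.0
    ratio: float = 1.0
    n_replicates: int = 1
    control_value: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("all doses must be positive")
        for v in np.atleast_1d(self.m_true):
            if v <= 0:
                raise ValueError("m_true must be positive")
        for v in np.atleast_1d(self.dm_true):
            if v <= 0:
                raise ValueError("dm_true must be positive")
        if self.synergy_alpha <= 0 or self.ratio <= 0:
            raise ValueError("synergy_alpha and ratio must be positive")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be non-negative")


def _per_drug(value, n_drugs: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n_drugs)
    if arr.size != n_drugs:
        raise ValueError(f"expected scalar or {n_drugs} values, got {arr.size}")
    return arr


def _median_effect_fa(dose: float, m: float, dm: float) -> float:
    q = (dose / dm) ** m
    return q / (1.0 + q)


def _loewe_fa(doses: np.ndarray, m: np.ndarray, dm: np.ndarray, alpha: float) -> float:
    """Solve sum_i D_i / Dx_i(fa) = 1/alpha for fa; the sum is decreasing in fa."""

    def g(fa: float) -> float:
        dx = dm * (fa / (1.0 - fa)) ** (1.0 / m)
        return float(np.sum(doses / dx)) - 1.0 / alpha

    lo, hi = 1e-12, 1.0 - 1e-12
    if g(lo) < 0 or g(hi) > 0:
        raise ValueError(
            "cannot bracket the combination fa: combo doses are far outside "
            "the response range of the median-effect curves"
        )
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=1e-14))


def gen_doseresponse(spec: SimDoseSpec, n_drugs: int = 1) -> tuple[pd.DataFrame, float]:
    """Generate a dose-response/combination table and the ground-truth CI.

    Returns a table in the standard dialect (``drug1_dose .. drug3_dose``,
    ``effect_type``, ``effect_value``, ``control_value``, ``batch``) holding
    single-drug curves for every drug and, for ``n_drugs >= 2``,
    constant-ratio combination rows.  Ground-truth CI is ``1/synergy_alpha``
    (1.0 for a single drug).
    """
    if n_drugs not in (1, 2, 3):
        raise ValueError("n_drugs must be 1, 2 or 3")
    rng = np.random.default_rng(spec.seed)
    m = _per_drug(spec.m_true, n_drugs)
    dm = _per_drug(spec.dm_true, n_drugs)

    def observed_x(fa: float) -> float:
        x = spec.control_value * (1.0 - fa)
        if spec.cv_noise > 0:
            x *= max(1.0 + spec.cv_noise * rng.standard_normal(), 1e-6)
        return x

    records = []
    for i in range(n_drugs):
        for d in spec.doses:
            for rep in range(spec.n_replicates):
                fa = _median_effect_fa(d, m[i], dm[i])
                dose_cols = [0.0, 0.0, 0.0]
                dose_cols[i] = d
                records.append(dose_cols + ["cell_number", observed_x(fa),
                                            spec.control_value, f"single_drug{i + 1}"])
    if n_drugs >= 2:
        for d in spec.doses:
            combo = np.array([d] + [spec.ratio * d] * (n_drugs - 1))
            fa = _loewe_fa(combo, m, dm, spec.synergy_alpha)
            for rep in range(spec.n_replicates):
                dose_cols = list(combo) + [0.0] * (3 - n_drugs)
                records.append(dose_cols + ["cell_number", observed_x(fa),
                                            spec.control_value, "combo"])

    table = pd.DataFrame(
        records,
        columns=["drug1_dose", "drug2_dose", "drug3_dose",
                 "effect_type", "effect_value", "control_value", "batch"],
    )
    truth_ci = 1.0 / spec.synergy_alpha if n_drugs >= 2 else 1.0
    return table, truth_ci
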