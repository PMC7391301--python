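"""Core in-memory containers shared across the pipeline stages.

Expression data is held as a genes x samples :class:`pandas.DataFrame` of
log-scale intensities together with a per-sample condition label; pooled-screen
counts as an shRNA x sample DataFrame with an shRNA->gene map and sample
metadata.  Networks are plain :class:`networkx.Graph` objects throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ScreenCounts",
    "MedianEffectFit",
    "ComboPoint",
    "SynergyAssessment",
    "HubResult",
    "ConsensusResult",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with a two-level condition label.

    Parameters
    ----------
    values : DataFrame
        Rows are gene ids, columns sample ids, entries log-scale intensities.
    condition : Series
        One label per sample (index must match ``values.columns``); exactly
        two levels, each with at least 3 samples.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = self.condition[self.condition.isna()].index.tolist()
            raise ValueError(f"samples without condition label: {missing}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        counts = self.condition.value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly 2 condition levels, got {list(counts.index)}")
        if (counts < 3).any():
            raise ValueError("every condition level needs >= 3 samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def levels(self) -> list[str]:
        return sorted(self.condition.unique())

    def samples_of(self, level: str) -> list[str]:
        return list(self.condition.index[self.condition == level])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[sample_ids], self.condition.loc[sample_ids])


@dataclass
class ScreenCounts:
    """Pooled-screen read counts: shRNA x sample, with gene map and metadata.

    ``samples`` is indexed by sample id with columns ``cell_line``,
    ``timepoint`` (``T0`` or ``tumor``) and ``replicate``.
    """

    counts: pd.DataFrame
    gene_of: pd.Series
    samples: pd.DataFrame
    log_scale: bool = False  # log-transformed tables may hold negatives

    def __post_init__(self) -> None:
        if not self.log_scale and (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_of = self.gene_of.reindex(self.counts.index)
        if self.gene_of.isna().any():
            missing = self.gene_of[self.gene_of.isna()].index.tolist()
            raise ValueError(f"shRNAs without gene assignment: {missing}")
        self.samples = self.samples.reindex(self.counts.columns)
        if self.samples.isna().any().any():
            raise ValueError("sample metadata incomplete for some count columns")
        bad = set(self.samples["timepoint"]) - {"T0", "tumor"}
        if bad:
            raise ValueError(f"unknown timepoints: {sorted(bad)}")
        for line, meta in self.samples.groupby("cell_line"):
            tps = set(meta["timepoint"])
            if "tumor" in tps and "T0" not in tps:
                raise ValueError(f"cell line {line!r} has tumor samples but no T0")

    @property
    def shrna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.samples["cell_line"].unique())

    def tumor_samples(self, cell_line: str) -> list[str]:
        m = (self.samples["cell_line"] == cell_line) & (self.samples["timepoint"] == "tumor")
        return list(self.samples.index[m])

    def t0_samples(self, cell_line: str) -> list[str]:
        m = (self.samples["cell_line"] == cell_line) & (self.samples["timepoint"] == "T0")
        return list(self.samples.index[m])


@dataclass
class MedianEffectFit:
    """Median-effect parameters from the linearised fit.

    fa/(1-fa) = (D/Dm)^m, fitted as log10(fa/(1-fa)) ~ m*log10(D) - m*log10(Dm).
    """

    drug: str
    m: float
    dm: float
    r_fit: float
    n_points_used: int

    def __post_init__(self) -> None:
        if not self.dm > 0:
            raise ValueError("Dm must be positive")
        if self.n_points_used < 2:
            raise ValueError("median-effect fit needs >= 2 points")


@dataclass
class ComboPoint:
    """One combination measurement: doses, effect level, CI and per-drug DRI."""

    doses: dict[str, float]
    fa: float
    dx: dict[str, float]
    ci: float
    dri: dict[str, float]


@dataclass
class SynergyAssessment:
    """Fa-CI points per combo orientation plus the potent-synergy call."""

    points: dict[str, list[ComboPoint]]
    potent: bool
    fa_min: float = 0.7
    ci_max: float = 0.7


@dataclass
class HubResult:
    """Per-hub disruption statistic S = mean over partners |r_A - r_B|."""

    hub_id: str
    partner_ids: list[str]
    score: float
    n_partners_used: int
    p_value: float = float("nan")

    @property
    def usable(self) -> bool:
        return self.n_partners_used > 0 and np.isfinite(self.score)


@dataclass
class ConsensusResult:
    """Significant hubs per subsample run and their intersection."""

    runs: list[set[str]]
    alpha: float
    subsample_fraction: float
    per_run_results: list[dict[str, HubResult]] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def disrupted_hubs(self) -> set[str]:
        out = set(self.runs[0])
        for r in self.runs[1:]:
            out &= r
        return out
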