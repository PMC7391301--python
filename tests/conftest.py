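import numpy as np
import pandas as pd
import pytest

import rbscreen as rb
from rbscreen.containers import ExpressionMatrix, ScreenCounts


@pytest.fixture(scope="session")
def disrupted_expression():
    """100-hub dataset, 5 disrupted (r 0.9 -> -0.9), 60 + 60 samples."""
    spec = rb.SimExpressionSpec(
        n_hubs=100, partners_per_hub=5, n_tumor=60, n_normal=60,
        r_normal=0.9, r_tumor_disrupted=-0.9,
        disrupted_hub_ids=frozenset(range(5)), seed=1,
    )
    expr, net, truth = rb.gen_expression(spec)
    return expr, net, truth


@pytest.fixture(scope="session")
def null_screen():
    """Null pooled screen: 10,000 shRNAs, 6 tumor reps, no depletion."""
    spec = rb.SimScreenSpec(n_genes=2500, shrnas_per_gene=4, n_tumor_reps=6,
                            seed=1)
    counts, depleted, outliers = rb.gen_screen(spec)
    assert not depleted and not outliers
    return counts


def make_expression(tumor: np.ndarray, normal: np.ndarray, gene_ids):
    """Assemble an ExpressionMatrix from per-condition gene x sample blocks."""
    n_t, n_n = tumor.shape[1], normal.shape[1]
    samples = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
    values = pd.DataFrame(np.hstack([tumor, normal]), index=gene_ids,
                          columns=samples)
    condition = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples)
    return ExpressionMatrix(values=values, condition=condition)


def make_screen(tumor: np.ndarray, t0: np.ndarray, shrna_ids, gene_of,
                cell_line: str = "L1", log_scale: bool = False) -> ScreenCounts:
    """Assemble a one-line ScreenCounts from a tumor block and T0 column."""
    n_reps = tumor.shape[1]
    t0_id = f"{cell_line}_T0"
    tumor_ids = [f"{cell_line}_tumor_{k + 1}" for k in range(n_reps)]
    counts = pd.DataFrame(np.column_stack([t0, tumor]), index=shrna_ids,
                          columns=[t0_id] + tumor_ids)
    samples = pd.DataFrame(
        {"cell_line": cell_line,
         "timepoint": ["T0"] + ["tumor"] * n_reps,
         "replicate": list(range(n_reps + 1))},
        index=[t0_id] + tumor_ids,
    )
    return ScreenCounts(counts=counts, gene_of=pd.Series(gene_of, index=shrna_ids),
                        samples=samples, log_scale=log_scale)
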