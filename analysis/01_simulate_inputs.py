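"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the study design at its published scale: a 21-tumor / 12-normal
two-condition expression matrix over 100 hubs (5 of them with disrupted
hub-partner co-expression in tumors), a pooled shRNA screen with 6 tumor
replicates and 5 truly depleted genes among 100, and a two-drug
constant-ratio combination experiment with ground-truth CI = 0.5.

Writes everything under results/simulated/ in the pipeline's TSV/CSV
dialects, truth files alongside.
"""

from pathlib import Path

import rbscreen as rb
from rbscreen import io as rio

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    expr_spec = rb.SimExpressionSpec(
        n_hubs=100, partners_per_hub=5, n_tumor=21, n_normal=12,
        r_normal=0.9, r_tumor_disrupted=-0.9,
        disrupted_hub_ids=frozenset(range(5)), seed=SEED,
    )
    expr, net, truth = rb.gen_expression(expr_spec)
    rio.write_expression(expr, OUT / "expression.tsv", OUT / "expression_samples.tsv")
    rio.write_network(net, OUT / "network.tsv")
    (OUT / "expression_truth.tsv").write_text(
        "disrupted_hub\n" + "".join(f"{h}\n" for h in sorted(truth)))
    print(f"expression: {expr.values.shape[0]} genes x "
          f"{expr.values.shape[1]} samples; {len(truth)} disrupted hubs")

    screen_spec = rb.SimScreenSpec(
        n_genes=100, shrnas_per_gene=4, n_tumor_reps=6,
        depleted_gene_ids=frozenset(range(5)), depletion_factor=0.1,
        outlier_rate=0.01, outlier_factor=50.0, seed=SEED,
    )
    counts, depleted, outliers = rb.gen_screen(screen_spec, cell_line="Y79sim")
    rio.write_counts(counts, OUT / "screen_counts.tsv", OUT / "screen_samples.tsv")
    (OUT / "screen_truth.tsv").write_text(
        "depleted_gene\n" + "".join(f"{g}\n" for g in sorted(depleted)))
    print(f"screen: {len(counts.shrna_ids)} shRNAs, {len(depleted)} depleted "
          f"genes, {len(outliers)} injected outlier cells")

    dose_spec = rb.SimDoseSpec(
        m_true=1.0, dm_true=10.0, doses=(1.0, 3.0, 10.0, 30.0, 100.0),
        synergy_alpha=2.0, ratio=0.5, cv_noise=0.05, n_replicates=3,
        seed=SEED,
    )
    table, truth_ci = rb.gen_doseresponse(dose_spec, n_drugs=2)
    rio.write_doseresponse(table, OUT / "doseresponse.csv")
    print(f"dose-response: {len(table)} rows, ground-truth CI = {truth_ci}")


if __name__ == "__main__":
    main()
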