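"""Generate the synthetic study inputs.

Writes the benchmark expression compendium (10 regulon-sized modules,
100 conditions in duplicate, contaminated genes), its GO-style
annotations and ground truth, plus a scale-free directed gold-standard
regulatory network with two sigma-factor-like hub regulators — the
simulated stand-ins for a microarray compendium and a RegulonDB-style
export.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from gcnbench import io as gio
from gcnbench.pipeline import BENCHMARK_SIM, stage_seed
from gcnbench.simulate import (
    simulate_annotations,
    simulate_expression,
    simulate_regulatory_network,
)
import dataclasses

SEED = 1
OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "01_simulate")


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    meta = {"seed": SEED}
    cfg = dataclasses.replace(BENCHMARK_SIM, seed=stage_seed(SEED, "simulate"))
    matrix, design, truth = simulate_expression(cfg)
    annotations = simulate_annotations(truth, n_terms=2 * cfg.n_modules + 4,
                                       frac_correct=0.9,
                                       seed=stage_seed(SEED, "annotations"))
    gold = simulate_regulatory_network(500, 2, seed=stage_seed(SEED, "gold"),
                                       hub_out_degree=120)

    gio.write_expression(matrix, os.path.join(OUTDIR, "expression.tsv"), meta)
    gio.write_design(design, os.path.join(OUTDIR, "design.tsv"), meta)
    gio.write_annotations(annotations, os.path.join(OUTDIR, "annotations.tsv"), meta)
    gio.write_truth(truth, OUTDIR, meta)
    gio.write_regnet(gold, os.path.join(OUTDIR, "gold_standard.tsv"), meta)

    sizes = sorted((len(m) for m in truth.modules.values()), reverse=True)
    print(f"compendium: {matrix.shape[0]} genes x {matrix.shape[1]} samples "
          f"({cfg.n_conditions} conditions x {cfg.n_replicates} replicates)")
    print(f"planted modules ({len(sizes)}): sizes {sizes}")
    print(f"contaminated: {len(truth.noisy_genes)} noisy, "
          f"{len(truth.low_signal_genes)} low-signal genes")
    print(f"gold standard: {len(gold.nodes)} genes, {len(gold.edges)} directed edges, "
          f"max out-degree {max(gold.out_degree().values())}")


if __name__ == "__main__":
    main()
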