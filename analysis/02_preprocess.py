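"""Filter contaminated genes and collapse replicates.

Reads the simulated compendium, removes genes with noisy replicate
behavior (median replicate CV above the cutoff) or signal below the
detection floor, collapses replicates to per-condition medians, and
reports how well the filter recovered the genes that were deliberately
contaminated by the generator.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from gcnbench import io as gio
from gcnbench.preprocess import aggregate_replicates, filter_genes

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
INDIR = os.path.join(BASE, "01_simulate")
OUTDIR = os.path.join(BASE, "02_preprocess")


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    matrix = gio.read_expression(os.path.join(INDIR, "expression.tsv"))
    design = gio.read_design(os.path.join(INDIR, "design.tsv"))
    flagged = {}
    with open(os.path.join(INDIR, "truth_flags.tsv")) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, flag = line.strip().split("\t")
            flagged[gene] = flag

    filtered, removed = filter_genes(matrix, design, cv_max=0.5, low_quantile=0.05)
    aggregated = aggregate_replicates(filtered, design)
    gio.write_expression(aggregated, os.path.join(OUTDIR, "expression.tsv"))
    with open(os.path.join(OUTDIR, "removed_genes.tsv"), "w") as fh:
        fh.write("gene\treason\n")
        for gene, reason in removed:
            fh.write(f"{gene}\t{reason}\n")

    removed_set = {g for g, _ in removed}
    low = {g for g, f in flagged.items() if f == "low_signal"}
    print(f"kept {aggregated.shape[0]} genes x {aggregated.shape[1]} conditions; "
          f"removed {len(removed)}")
    if low:
        print(f"low-signal recovery: {len(removed_set & low)}/{len(low)} "
              "planted low-signal genes caught by the detection-floor filter")
    print("(noisy genes at tenfold variance sit below the default CV cutoff of "
          "0.5 on this log-signal scale; they are retained and handled by the "
          "association thresholds downstream)")


if __name__ == "__main__":
    main()
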