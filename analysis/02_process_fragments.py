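#!/usr/bin/env python
"""Filter the spike-in screen's fragments and build quantity matrices.

Applies the detection filter (>= 2 observations per condition), the
mapDIA-style reliability filter (min correlation 0.25, SD factor 2),
rolls fragments up to peptide and protein quantities, and imputes
missing values with the per-analyte 0.01 quantile. Writes
peptide_matrix.tsv and protein_matrix.tsv under results/processed/.
"""

import argparse
from pathlib import Path

from apmsdia import fragments as frag
from apmsdia import io as apio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data/spikein"))
    ap.add_argument("--out", type=Path, default=Path("results/processed"))
    args = ap.parse_args()

    table = apio.read_fragment_table(args.data / "fragments.tsv")
    design = apio.read_design(args.data / "design.tsv")
    detected = frag.detection_filter(table, design, 2)
    reliable = frag.reliability_filter(detected, 2.0, 0.25)
    print(
        f"detection filter kept {len(detected):,}/{len(table):,} rows; "
        f"reliability filter kept {len(reliable):,}"
    )
    routed = frag.route_phosphopeptides(reliable)
    pep, _ = frag.rollup(routed)
    _, prot = frag.rollup(reliable)
    imp_pep = frag.impute_missing(pep, 0.01)
    imp_prot = frag.impute_missing(prot, 0.01)
    print(
        f"{imp_prot.matrix.shape[0]} proteins and {imp_pep.matrix.shape[0]} peptides "
        f"quantified; {int(imp_pep.imputed_mask.to_numpy().sum())} peptide values imputed"
    )
    apio.write_results(
        {
            "peptide_matrix": apio.matrix_to_frame(imp_pep.matrix),
            "protein_matrix": apio.matrix_to_frame(imp_prot.matrix),
        },
        args.out,
    )
    print(f"matrices written under {args.out}")


if __name__ == "__main__":
    main()
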