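"""Motif, functional-category and OCR/gene pair enrichment per module.

Promoter motif hits of each expression module are tested against all
other promoters (upper-tail hypergeometric, BH q < 0.1); functional terms
by one-sided Fisher (terms with >= 5 annotated genes); OCR/gene pairs by
module-pair hypergeometric enrichment.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from plangrn import io, pipeline


def main() -> None:
    common.ensure_dirs()
    for kind in ("motif", "motif-ocr", "function", "pairs"):
        pipeline.stage_enrich(common.RUN, kind)
    mot = pd.read_csv(common.RUN / "enrich_motif_expression.tsv", sep="\t")
    top = (
        mot.sort_values("p").groupby("unit").head(1)
        [["unit", "term", "fg_hits", "fg_total", "q", "significant"]]
        .sort_values("unit")
    )
    io.write_tsv(top, common.TABLES / "05_top_motifs_per_module.tsv", index=False)
    print("Top promoter motif per expression module:")
    print(top.to_string(index=False))
    pairs = pd.read_csv(common.RUN / "enrich_pairs.tsv", sep="\t")
    sig = pairs[pairs["q"] < 0.05].sort_values("q")
    io.write_tsv(sig, common.TABLES / "05_significant_ocr_gene_pairs.tsv", index=False)
    print(f"\n{len(sig)} significant gene-module/OCR-module pairs (q < 0.05); "
          "matched modules pair off on the diagonal.")


if __name__ == "__main__":
    main()
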