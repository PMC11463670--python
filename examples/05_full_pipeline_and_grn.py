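"""Run the full pipeline end-to-end and read out the TF regulatory
network and ligand-receptor summary.

Equivalent shell command:
    pgcmultiome all --data-dir data/ --outdir out/ --seed 1
"""

import tempfile
from pathlib import Path

import pandas as pd

from pgcmultiome.pipeline import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    out = run_pipeline(["all"], tmp / "data", tmp / "out", seed=1)

    cands = pd.read_csv(out / "grn" / "tf_candidates.tsv", sep="\t")
    print("TF triage (sex-DE, germline-enriched, motif-enriched, activity z > 0):")
    print(
        cands[["tf", "is_de_between_sexes", "is_germline_enriched",
               "motif_enriched", "mean_motif_activity_z", "passes_all"]]
        .to_string(index=False)
    )

    edges = pd.read_csv(out / "grn" / "network_edges.tsv", sep="\t")
    summary = pd.read_csv(out / "grn" / "summary.tsv", sep="\t")
    print(f"\nnetwork edges: {len(edges)}")
    print(summary.to_string(index=False))

    venn = pd.read_csv(out / "comm" / "venn.tsv", sep="\t")
    print("\nsignificant ligand-receptor interactions (XX-only / XY-only / shared):")
    print(venn.to_string(index=False))
# The per-TF percentage is the share of linked DEGs reached by that TF's
# motif-supported edges; the venn rows recover the planted sex-specific
# and shared signaling pairs.
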