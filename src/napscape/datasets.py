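"""Small published tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def transient_gene_table() -> pd.DataFrame:
    """The published list of transiently upregulated genes with their
    transcriptional-unit assignments (tu_id "NA" = no TU assigned).

    Columns: gene_id, category, product, tu_id (tu_id is NaN-free text;
    missing assignments carry the literal string "NA").
    """
    ref = resources.files("napscape.data") / "transient_upregulated_genes.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def transient_gene_summary() -> dict[str, int]:
    """Counts over the published transient gene list: genes, distinct TUs,
    and genes lacking a TU assignment."""
    df = transient_gene_table()
    tus = df.loc[df["tu_id"] != "NA", "tu_id"]
    return {
        "n_genes": len(df),
        "n_tus": int(tus.nunique()),
        "n_missing_tu": int((df["tu_id"] == "NA").sum()),
    }
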