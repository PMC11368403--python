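"""DEG calling and four-class temporal classification of upregulated genes.

Genes more than twofold up within the first hour of the shift (log2FC > 1,
strict) are split by their 1 h -> 4 h trajectory: ``transient`` if expression
falls back (log2FC < -0.5), ``continuous`` if it keeps rising (log2FC > 0.5),
``plateau`` otherwise (defined by exclusion). Genes not up within 1 h but
more than fourfold up by 4 h (log2FC > 2) are ``late``; everything else is
``none``. The union of the 1 h-upregulated set and the late set is the
"all upregulated" reference used by the enrichment layer.

All thresholds are strict inequalities ("more than twofold" excludes the
boundary) and live in :class:`DynamicsParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CLASSES = ("transient", "plateau", "continuous", "late", "none")


@dataclass
class DynamicsParams:
    """Fold-change/FDR thresholds for DEG calling and temporal classes."""

    up1_log2fc: float = 1.0       # >2x within 1 h gates the upregulated set
    transient_drop: float = -0.5  # 1->4 h log2FC below this: transient
    continuous_rise: float = 0.5  # 1->4 h log2FC above this: continuous
    late_log2fc: float = 2.0      # >4x within 4 h without the 1 h gate: late
    deg_log2fc: float = 1.0
    deg_fdr: float = 0.05
    up1_fdr: float | None = None  # optional FDR gate on the 1 h screen

    def __post_init__(self) -> None:
        if not self.transient_drop < 0 < self.continuous_rise:
            raise ValueError("need transient_drop < 0 < continuous_rise")


class ContrastTable:
    """Per-gene log2FC and FDR for named condition contrasts.

    Thin wrapper over a DataFrame with MultiIndex columns
    ``(contrast, {"log2fc", "fdr"})`` indexed by gene_id.
    """

    def __init__(self, frame: pd.DataFrame):
        if not isinstance(frame.columns, pd.MultiIndex):
            raise ValueError("expected MultiIndex columns (contrast, field)")
        fdr = frame.loc[:, (slice(None), "fdr")]
        if ((fdr < 0) | (fdr > 1)).any().any():
            raise ValueError("FDR values outside [0, 1]")
        self.frame = frame

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    @property
    def contrasts(self) -> list[str]:
        return sorted(self.frame.columns.get_level_values(0).unique())

    def column(self, contrast: str, field: str = "log2fc") -> pd.Series:
        if contrast not in self.frame.columns.get_level_values(0):
            raise KeyError(f"missing contrast column: {contrast}")
        return self.frame[(contrast, field)]

    # -- I/O: flat TSV with <contrast>.log2fc / <contrast>.fdr columns ------
    def to_tsv(self, path: str | Path) -> None:
        flat = self.frame.copy()
        flat.columns = [f"{c}.{f}" for c, f in flat.columns]
        flat.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContrastTable":
        flat = pd.read_csv(path, sep="\t", index_col="gene_id")
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.rsplit(".", 1)) for c in flat.columns]
        )
        flat.columns = cols
        return cls(flat)


def call_degs(
    table: ContrastTable, contrast: str, params: DynamicsParams | None = None
) -> pd.Series:
    """Per-gene {up, down, ns} at |log2FC| > threshold and FDR < alpha."""
    params = params or DynamicsParams()
    lfc = table.column(contrast, "log2fc")
    fdr = table.column(contrast, "fdr")
    sig = fdr < params.deg_fdr
    out = pd.Series("ns", index=table.genes, name=contrast)
    out[(lfc > params.deg_log2fc) & sig] = "up"
    out[(lfc < -params.deg_log2fc) & sig] = "down"
    return out


def classify_dynamics(
    table: ContrastTable, params: DynamicsParams | None = None
) -> tuple[pd.Series, pd.Index]:
    """Assign each gene a temporal class; return (classes, all_upregulated).

    ``all_upregulated`` is the union of the 1 h-upregulated genes and the
    late-upregulated genes.
    """
    params = params or DynamicsParams()
    lfc01 = table.column("t0_vs_t1", "log2fc")
    lfc14 = table.column("t1_vs_t4", "log2fc")
    lfc04 = table.column("t0_vs_t4", "log2fc")

    up1 = lfc01 > params.up1_log2fc
    if params.up1_fdr is not None:
        up1 &= table.column("t0_vs_t1", "fdr") < params.up1_fdr

    classes = pd.Series("none", index=table.genes, name="class")
    classes[up1] = "plateau"  # default within the up1 set, defined by exclusion
    classes[up1 & (lfc14 < params.transient_drop)] = "transient"
    classes[up1 & (lfc14 > params.continuous_rise)] = "continuous"
    late = ~up1 & (lfc04 > params.late_log2fc)
    classes[late] = "late"

    all_up = table.genes[up1 | late]
    return classes, all_up


def class_counts(classes: pd.Series) -> dict[str, int]:
    return {k: int((classes == k).sum()) for k in CLASSES}
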