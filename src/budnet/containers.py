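"""Shared in-memory containers for expression data.

The pipeline passes a single :class:`ExpressionMatrix` between stages and
tracks which transformations have been applied via a ``layer`` tag, so a
matrix is never TMM-normalised or batch-corrected twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

#: Recognised transformation states, in pipeline order.
LAYERS = ("counts", "cpm_tmm", "log2", "batch_corrected")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Raw counts
        or normalised/log2 values depending on ``layer``.
    layer
        One of :data:`LAYERS`; tracks the transformation state.
    sample_meta
        Optional per-sample metadata (organ, timepoint_cu, batch, replicate),
        indexed by sample id and aligned with ``values.columns``.
    """

    values: pd.DataFrame
    layer: str = "counts"
    sample_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene id {dup!r}")
        if self.layer == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in a counts layer")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        """Return a copy carrying new values and an updated layer tag."""
        return replace(self, values=values, layer=layer)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        layer: str = "counts",
        meta_path: str | Path | None = None,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values=values, layer=layer, sample_meta=meta)
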