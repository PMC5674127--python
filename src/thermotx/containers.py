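"""Core in-memory containers shared by the analysis stages.

An :class:`ExpressionExperiment` bundles the per-gene read-count matrix with
the sample sheet (temperature, growth rate, replicate) and per-gene metadata
(length, COG categories).  Truth labels emitted by the simulators travel as
plain :class:`pandas.DataFrame` objects with a fixed column contract so that
recovery tests can join them against pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: one-letter COG functional categories used throughout (NC = not in COG)
COG_CATEGORIES = (
    "J", "K", "L", "D", "V", "T", "M", "N", "O", "C",
    "G", "E", "F", "H", "P", "I", "Q", "R", "S", "NC",
)

#: de_class values a simulated gene may carry
DE_CLASSES = ("null", "temp_responsive", "rate_linear", "mixed")

#: lgt_class values a simulated gene may carry
LGT_CLASSES = ("vertical", "transferred_K", "transferred_KM")


@dataclass
class ExpressionExperiment:
    """Count matrix plus sample and gene metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes x samples.  Index = gene ids,
        columns = sample ids.
    samples
        One row per sample (index = sample id) with columns
        ``temperature_C``, ``growth_rate_per_h``, ``replicate``.
    genes
        One row per gene (index = gene id) with columns ``length_nt`` and
        ``cog_categories`` (semicolon-separated one-letter codes).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise DataError("gene ids in the count matrix must be unique")
        if list(self.counts.columns) != list(self.samples.index):
            raise DataError("count matrix columns must match the sample sheet")
        if not self.counts.index.equals(self.genes.index):
            raise DataError("count matrix rows must match the gene table")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataError("counts must be non-negative")
        if (vals.sum(axis=0) <= 0).any():
            raise DataError("every sample must have a positive column total")
        if (self.genes["length_nt"].to_numpy() <= 0).any():
            raise DataError("gene lengths must be positive")
        for col in ("temperature_C", "growth_rate_per_h", "replicate"):
            if col not in self.samples.columns:
                raise DataError(f"sample sheet is missing column {col!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.samples["temperature_C"].unique())

    def samples_at(self, temperature: float) -> list[str]:
        """Sample ids measured at the given temperature."""
        mask = self.samples["temperature_C"] == temperature
        return list(self.samples.index[mask])


def empty_truth(gene_ids, temperatures) -> pd.DataFrame:
    """All-null truth table: one row per gene, zero offsets and slopes."""
    df = pd.DataFrame({"gene_id": list(gene_ids)})
    df["de_class"] = "null"
    for t in temperatures:
        df[f"offset_log2_{t:g}C"] = 0.0
    df["rate_slope"] = 0.0
    df["lgt_class"] = pd.NA
    return df.set_index("gene_id")


def validate_truth(truth: pd.DataFrame) -> None:
    """Check the truth-label contract (partition + null consistency)."""
    if not truth.index.is_unique:
        raise DataError("truth labels must list every gene exactly once")
    bad = ~truth["de_class"].isin(DE_CLASSES)
    if bad.any():
        raise DataError(f"unknown de_class values: {truth['de_class'][bad].unique()}")
    offset_cols = [c for c in truth.columns if c.startswith("offset_log2_")]
    nulls = truth["de_class"] == "null"
    if nulls.any():
        if (truth.loc[nulls, offset_cols].to_numpy() != 0).any():
            raise DataError("null genes must have zero fold offsets")
        if (truth.loc[nulls, "rate_slope"].to_numpy() != 0).any():
            raise DataError("null genes must have zero rate slope")
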