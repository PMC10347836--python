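"""Gene x sample containers for one omics layer.

An :class:`OmicsMatrix` holds a pandas DataFrame of values (genes as rows)
together with per-column sample metadata (stage, replicate, batch).  Missing
cells are NaN; for the protein layer NaN means "not detected by LC-MS/MS",
while FPKM layers keep explicit zeros as detected measurements.

Layers
------
``protein_log2_ibaq``
    log2-transformed iBAQ intensities; real-valued, NaN = not detected.
``rpf_fpkm`` / ``mrna_fpkm``
    ribosome-protected-fragment and mRNA FPKM; nonnegative, 0 is a value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .stages import DEFAULT_SERIES, StageSeries

LAYERS = ("protein_log2_ibaq", "rpf_fpkm", "mrna_fpkm")
FPKM_LAYERS = ("rpf_fpkm", "mrna_fpkm")


def sample_meta(
    stages: Iterable[str],
    replicates: Iterable[int],
    batches: Iterable[object] | None = None,
    names: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Build a column-metadata frame (index = column name)."""
    stages = list(stages)
    replicates = list(replicates)
    if batches is None:
        batches = [None] * len(stages)
    else:
        batches = list(batches)
    if names is None:
        names = [f"{s}_rep{r}" for s, r in zip(stages, replicates)]
    meta = pd.DataFrame(
        {"stage": stages, "replicate": replicates, "batch": batches},
        index=pd.Index(list(names), name="sample"),
    )
    return meta


@dataclass
class OmicsMatrix:
    """Values for one layer plus per-column sample annotation.

    ``values.columns`` must equal ``meta.index``.  A stage-averaged matrix
    has one column per stage and ``meta.replicate`` is NA.
    """

    layer: str
    values: pd.DataFrame
    meta: pd.DataFrame
    series: StageSeries = DEFAULT_SERIES

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer: {self.layer!r}")
        if not self.values.columns.equals(self.meta.index):
            raise InputError("values columns and meta index must match")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dups[:5]}")
        known = set(self.series.labels)
        bad = set(self.meta["stage"]) - known
        if bad:
            raise InputError(f"unknown stage label(s): {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def stages_present(self) -> list[str]:
        present = set(self.meta["stage"])
        return [s for s in self.series.labels if s in present]

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True = measured)."""
        return self.values.notna()

    def columns_for_stage(self, stage: str) -> pd.Index:
        return self.meta.index[self.meta["stage"] == stage]

    @property
    def is_stage_averaged(self) -> bool:
        return self.meta["replicate"].isna().all() and not self.meta["stage"].duplicated().any()

    def subset_genes(self, genes: Iterable[str]) -> "OmicsMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.values.index)
        if len(missing):
            raise InputError(f"genes not in matrix: {missing[:5].tolist()}")
        return replace(self, values=self.values.loc[genes])

    # -- transforms --------------------------------------------------------
    def imputed(self, shift: float = 1.0) -> pd.DataFrame:
        """Protein values with NaN replaced by (global detected minimum - shift).

        "Not detected" on the protein layer is read as "below the LC-MS/MS
        sensitivity limit", so missing cells are filled with a value just
        below the lowest detected log2 intensity.  FPKM layers are returned
        with NaN -> 0 (absence of signal).
        """
        if self.layer in FPKM_LAYERS:
            return self.values.fillna(0.0)
        floor = np.nanmin(self.values.to_numpy()) - shift
        return self.values.fillna(floor)

    def log_values(self, pseudocount: float = 1.0, shift: float = 1.0) -> pd.DataFrame:
        """Values on a log2 scale: identity for protein, log2(x + pseudocount) for FPKM."""
        if self.layer in FPKM_LAYERS:
            return np.log2(self.values.fillna(0.0) + pseudocount)
        return self.imputed(shift=shift)

    def stage_averaged_meta(self, stages: list[str]) -> pd.DataFrame:
        return sample_meta(stages, [np.nan] * len(stages), names=stages)


def stage_matrix(
    layer: str,
    values: pd.DataFrame,
    series: StageSeries = DEFAULT_SERIES,
) -> OmicsMatrix:
    """Wrap a stage-averaged DataFrame (columns = stage labels) as an OmicsMatrix."""
    meta = sample_meta(list(values.columns), [np.nan] * values.shape[1], names=list(values.columns))
    return OmicsMatrix(layer, values, meta, series)
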