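"""Proteome pre-processing: batch correction, replicate merging, gene universe.

Label-free iBAQ intensities acquired in separate LC-MS/MS batches carry
additive offsets on the log2 scale.  Because fully grown oocytes (FGOs)
were included in every batch, they anchor the correction: using proteins
detected in all batches, each batch's median FGO intensity is compared to
the reference batch and the difference subtracted from every sample in
that batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CorrectionError, InputError
from .matrix import OmicsMatrix, sample_meta, stage_matrix

__all__ = [
    "BatchFactors",
    "compute_batch_factors",
    "apply_batch_correction",
    "merge_replicates",
    "replicate_matrix_with_derived_fgo",
    "fgo_derived_detection",
    "filter_gene_universe",
]

#: FGO replicate pairing used to form two derived replicates: the study's
#: four FGO runs pair (batch-1, batch-2) and (batch-3, batch-3).
DEFAULT_FGO_POLICY: tuple[tuple[int, int], ...] = ((1, 2), (3, 4))


@dataclass(frozen=True)
class BatchFactors:
    """Additive log2 offsets per batch; the reference batch has offset 0."""

    reference_batch: object
    offsets: Mapping[object, float]

    def __post_init__(self) -> None:
        if abs(self.offsets[self.reference_batch]) > 1e-12:
            raise CorrectionError("reference batch offset must be 0")


def compute_batch_factors(
    protein: OmicsMatrix,
    anchor_stage: str = "FGO",
    reference_batch: object = 1,
) -> BatchFactors:
    """Estimate per-batch offsets from the anchor stage.

    For each batch, proteins detected in every batch's anchor-stage
    samples are reduced to one value per batch (mean over that batch's
    detected anchor replicates); the offset is the difference of the
    per-batch medians (across those common proteins) relative to the
    reference batch.
    """
    meta = protein.meta
    anchor = meta[meta["stage"] == anchor_stage]
    if anchor.empty:
        raise CorrectionError(f"anchor stage {anchor_stage!r} not present")
    batches = anchor["batch"].unique().tolist()
    if len(batches) < 2:
        raise CorrectionError("anchor stage must be present in at least two batches")
    if reference_batch not in batches:
        raise CorrectionError(f"reference batch {reference_batch!r} has no anchor samples")

    # per-protein, per-batch mean over detected anchor replicates
    per_batch = {}
    for b in batches:
        cols = anchor.index[anchor["batch"] == b]
        per_batch[b] = protein.values[cols].mean(axis=1)  # NaN if none detected
    anchor_frame = pd.DataFrame(per_batch)
    common = anchor_frame.dropna()
    if common.empty:
        raise CorrectionError("no anchor proteins detected in all batches")

    ref_median = common[reference_batch].median()
    offsets = {b: float(common[b].median() - ref_median) for b in batches}
    offsets[reference_batch] = 0.0
    # batches with no anchor samples cannot be corrected; leave them out so
    # apply_batch_correction raises if such a batch appears in the data
    return BatchFactors(reference_batch, offsets)


def apply_batch_correction(protein: OmicsMatrix, factors: BatchFactors) -> OmicsMatrix:
    """Subtract each column's batch offset; detection mask is unchanged."""
    corrected = protein.values.copy()
    for name, row in protein.meta.iterrows():
        b = row["batch"]
        if b not in factors.offsets:
            raise CorrectionError(f"no offset for batch {b!r} (column {name!r})")
        corrected[name] = corrected[name] - factors.offsets[b]
    return replace(protein, values=corrected)


def fgo_derived_detection(
    protein: OmicsMatrix,
    fgo_policy: Sequence[Sequence[int]] = DEFAULT_FGO_POLICY,
    stage: str = "FGO",
) -> pd.DataFrame:
    """Detection of each derived FGO replicate (gene x derived-replicate bool).

    A derived replicate pools a pair of raw replicates and counts as
    detected if the protein is detected in at least one member.
    """
    meta = protein.meta
    fgo_cols = meta[meta["stage"] == stage]
    out = {}
    for d, pair in enumerate(fgo_policy, start=1):
        cols = [fgo_cols.index[fgo_cols["replicate"] == r][0] for r in pair]
        out[d] = protein.values[cols].notna().any(axis=1)
    return pd.DataFrame(out)


def _derived_fgo_values(
    protein: OmicsMatrix, fgo_policy: Sequence[Sequence[int]], stage: str = "FGO"
) -> pd.DataFrame:
    """Derived FGO replicate values: mean over detected members of each pair."""
    meta = protein.meta
    fgo_cols = meta[meta["stage"] == stage]
    out = {}
    for d, pair in enumerate(fgo_policy, start=1):
        cols = [fgo_cols.index[fgo_cols["replicate"] == r][0] for r in pair]
        out[f"{stage}_rep{d}"] = protein.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def replicate_matrix_with_derived_fgo(
    protein: OmicsMatrix,
    fgo_policy: Sequence[Sequence[int]] = DEFAULT_FGO_POLICY,
) -> OmicsMatrix:
    """Replicate-level matrix in which the four FGO runs are replaced by the
    two derived replicates, matching the layout used for all other stages."""
    derived = _derived_fgo_values(protein, fgo_policy)
    keep = protein.meta[protein.meta["stage"] != "FGO"]
    values = pd.concat([derived, protein.values[keep.index]], axis=1)
    meta = pd.concat(
        [
            sample_meta(["FGO"] * len(derived.columns), range(1, len(derived.columns) + 1),
                        names=list(derived.columns)),
            keep,
        ]
    )
    return OmicsMatrix(protein.layer, values, meta, protein.series)


def merge_replicates(
    matrix: OmicsMatrix,
    fgo_policy: Sequence[Sequence[int]] | None = None,
) -> OmicsMatrix:
    """Average replicates into one column per stage.

    The mean uses only replicates in which the gene was detected; a stage
    is missing iff all its replicates are missing.  For the protein layer,
    FGO replicates are first paired into two derived replicates per
    ``fgo_policy`` (each the detected-mean of its pair), then averaged.
    """
    work = matrix
    if matrix.layer == "protein_log2_ibaq" and "FGO" in matrix.stages_present:
        policy = DEFAULT_FGO_POLICY if fgo_policy is None else fgo_policy
        n_fgo = (matrix.meta["stage"] == "FGO").sum()
        if n_fgo > 2:
            work = replicate_matrix_with_derived_fgo(matrix, policy)
    stages = work.stages_present
    cols = {}
    for s in stages:
        sc = work.columns_for_stage(s)
        if len(sc) == 0:
            raise InputError(f"stage {s!r} has no replicates")
        cols[s] = work.values[sc].mean(axis=1)
    return stage_matrix(work.layer, pd.DataFrame(cols, index=work.genes), work.series)


def filter_gene_universe(
    protein: OmicsMatrix,
    rpf: OmicsMatrix,
    mrna: OmicsMatrix,
    fgo_policy: Sequence[Sequence[int]] = DEFAULT_FGO_POLICY,
) -> pd.Index:
    """Genes retained for downstream analysis.

    A gene is kept if (i) its protein was detected in at least one sample,
    (ii) it does not fail the FGO consistency rule — detected in exactly
    one of the two derived FGO replicates — and (iii) it is detected
    (FPKM > 0) at one or more stages in the translatome or transcriptome.
    """
    shared = protein.genes.intersection(rpf.genes).intersection(mrna.genes)
    if shared.empty:
        raise InputError("protein and RNA layers share no gene ids")
    det = protein.detected().loc[shared].any(axis=1)
    n_fgo = (protein.meta["stage"] == "FGO").sum()
    if n_fgo >= 2 and len(fgo_policy) >= 2:
        fgo_det = fgo_derived_detection(protein, fgo_policy).loc[shared]
        inconsistent = fgo_det.sum(axis=1) == 1
    else:
        inconsistent = pd.Series(False, index=shared)
    rna_detected = (rpf.values.loc[shared].fillna(0) > 0).any(axis=1) | (
        mrna.values.loc[shared].fillna(0) > 0
    ).any(axis=1)
    keep = det & ~inconsistent & rna_detected
    return shared[keep]
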