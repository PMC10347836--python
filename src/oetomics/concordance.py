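"""Protein-translation/transcription concordance and its correlates.

Gene-wise concordance is the Spearman correlation between a gene's protein
trajectory and its RPF (or mRNA) trajectory over the seven stages, binned
into high (r > 0.5), medium (0.2 <= r <= 0.5) and low (r < 0.2).  The
boundary values, ambiguous in strict-inequality notation, are assigned to
the medium bin.  Change-level concordance correlates per-transition log2
changes across genes, including at a lag: protein changes often track
translation changes one or two stage transitions earlier.

The module also segments per-residue disorder scores into intrinsically
disordered regions (IDRs: runs of score > 0.5 longer than 30 residues) and
tests whether numeric or binary gene features (initial FGO abundance,
half-life, IDR presence) differ between concordance bins or trajectory
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu, spearmanr

from .errors import AnalysisError, InputError
from .matrix import FPKM_LAYERS, OmicsMatrix

__all__ = [
    "genewise_correlation",
    "change_matrix",
    "lagged_change_correlation",
    "lag_diagonal",
    "IdrSegment",
    "idr_segments",
    "feature_association",
]

BIN_LOW, BIN_HIGH = 0.2, 0.5


def _bin_correlation(r: float) -> str:
    if np.isnan(r):
        return "undefined"
    if r > BIN_HIGH:
        return "high"
    if r < BIN_LOW:
        return "low"
    return "medium"


def genewise_correlation(
    protein: OmicsMatrix,
    other: OmicsMatrix,
    min_stages: int = 3,
    use_imputed: bool = True,
    impute_shift: float = 1.0,
) -> tuple[pd.DataFrame, int]:
    """Per-gene Spearman between protein and another layer across stages.

    With ``use_imputed`` (default) undetected protein stages enter at the
    imputed floor value; otherwise only stages detected in both layers are
    used, and genes with fewer than ``min_stages`` such stages are skipped.
    Returns (table with r and bin per gene, number of genes skipped).
    """
    if not (protein.is_stage_averaged and other.is_stage_averaged):
        raise InputError("genewise_correlation expects stage-averaged matrices")
    shared = protein.genes.intersection(other.genes)
    stages = [s for s in protein.values.columns if s in set(other.values.columns)]
    if len(stages) < min_stages:
        raise AnalysisError("fewer than min_stages shared stages")
    pv = (
        protein.imputed(shift=impute_shift)
        if use_imputed
        else protein.values
    ).loc[shared, stages]
    ov = other.values.fillna(0.0).loc[shared, stages] if other.layer in FPKM_LAYERS else other.values.loc[shared, stages]

    rows = []
    n_skipped = 0
    for g in shared:
        x = pv.loc[g].to_numpy(dtype=float)
        y = ov.loc[g].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < min_stages:
            n_skipped += 1
            continue
        xs, ys = x[keep], y[keep]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            r = np.nan
        else:
            r = float(spearmanr(xs, ys).statistic)
        rows.append({"gene_id": g, "r": r, "bin": _bin_correlation(r)})
    table = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["r", "bin"]
    )
    return table, n_skipped


def change_matrix(matrix: OmicsMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2 change for each consecutive stage transition.

    Protein values are already log2; FPKM layers are log2(x + pseudocount)
    transformed first.  Columns are labelled ``"A->B"``.
    """
    if not matrix.is_stage_averaged:
        raise InputError("change_matrix expects a stage-averaged matrix")
    log_vals = matrix.log_values(pseudocount=pseudocount)
    stages = list(log_vals.columns)
    out = {}
    for a, b in zip(stages[:-1], stages[1:]):
        out[f"{a}->{b}"] = log_vals[b] - log_vals[a]
    return pd.DataFrame(out, index=matrix.genes)


def lagged_change_correlation(
    protein_changes: pd.DataFrame, other_changes: pd.DataFrame
) -> pd.DataFrame:
    """Transition x transition Spearman matrix of per-gene changes.

    Entry (i, j) correlates, across genes, the protein change at transition
    i with the other layer's change at transition j.  The sub-diagonals at
    offsets 1 and 2 (see :func:`lag_diagonal`) are the one- and two-stage
    lagging series.
    """
    shared = protein_changes.index.intersection(other_changes.index)
    if len(shared) < 3:
        raise AnalysisError("fewer than 3 shared genes")
    pc = protein_changes.loc[shared]
    oc = other_changes.loc[shared]
    out = pd.DataFrame(
        index=pd.Index(pc.columns, name="protein_transition"),
        columns=pd.Index(oc.columns, name="other_transition"),
        dtype=float,
    )
    for ti in pc.columns:
        for tj in oc.columns:
            out.loc[ti, tj] = spearmanr(pc[ti], oc[tj]).statistic
    return out


def lag_diagonal(corr: pd.DataFrame, lag: int = 0) -> pd.Series:
    """Series of entries where the other layer's transition precedes the
    protein transition by ``lag`` steps (lag 0 = synchronized diagonal)."""
    vals = {}
    for i, ti in enumerate(corr.index):
        j = i - lag
        if 0 <= j < corr.shape[1]:
            vals[ti] = corr.iloc[i, j]
    return pd.Series(vals, name=f"lag_{lag}")


@dataclass(frozen=True)
class IdrSegment:
    """Maximal disordered run, 1-based inclusive residue coordinates."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def idr_segments(
    scores: np.ndarray, cutoff: float = 0.5, min_len: int = 30
) -> tuple[list[IdrSegment], bool]:
    """Segment per-residue disorder scores into IDRs.

    An IDR is a maximal run of residues with score > ``cutoff`` that is
    strictly longer than ``min_len`` residues.  Returns the segment list
    and a has-IDR flag.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise InputError("empty score vector")
    if np.any((s < 0) | (s > 1)):
        raise InputError("scores must lie in [0, 1]")
    above = s > cutoff
    segments: list[IdrSegment] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > min_len:
                segments.append(IdrSegment(start + 1, i))
            start = None
    if start is not None and len(above) - start > min_len:
        segments.append(IdrSegment(start + 1, len(above)))
    return segments, bool(segments)


def feature_association(
    values: pd.Series,
    groups: pd.Series,
    binary: bool = False,
) -> pd.DataFrame:
    """Pairwise two-tailed group contrasts for a per-gene feature.

    Numeric features use the Wilcoxon rank-sum (Mann-Whitney U) test;
    binary features use a 2x2 contingency table with Fisher's exact test.
    Groups with fewer than 2 members are skipped (flagged in the output).
    """
    shared = values.index.intersection(groups.index)
    values = values.loc[shared].dropna()
    groups = groups.loc[values.index]
    labels = sorted(groups.dropna().unique().tolist(), key=str)
    if len(labels) < 2:
        raise AnalysisError("need at least two groups")
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            xa = values[groups == ga]
            xb = values[groups == gb]
            row = {"group_a": ga, "group_b": gb, "n_a": len(xa), "n_b": len(xb)}
            if len(xa) < 2 or len(xb) < 2:
                row.update({"statistic": np.nan, "p_value": np.nan, "skipped": True})
            elif binary:
                table = [
                    [int((xa > 0).sum()), int((xa <= 0).sum())],
                    [int((xb > 0).sum()), int((xb <= 0).sum())],
                ]
                odds, p = fisher_exact(table, alternative="two-sided")
                row.update({"statistic": odds, "p_value": float(p), "skipped": False})
            else:
                res = mannwhitneyu(xa, xb, alternative="two-sided")
                row.update(
                    {"statistic": float(res.statistic), "p_value": float(res.pvalue), "skipped": False}
                )
            rows.append(row)
    return pd.DataFrame(rows)
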