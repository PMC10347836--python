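"""Differential expression between consecutive stages and its attribution.

Differentially expressed proteins/genes (DEPs/DEGs) between two
consecutive stages are called by a two-fold change with a two-tailed
equal-variance Student's t-test at p < 0.05 on replicate log2 values
(translation-inhibition experiments use a four-fold rule).  Each protein
change is then attributed to the regulatory layer that could explain it:
an mRNA change of the same sign within the current or two preceding
transitions ("mRNA contributed"), else a same-sign RPF change in that
window ("RPF only" — mRNA-independent translational control), else
unexplained (candidate post-translational regulation).

No multiple-testing correction is applied: calls use the raw p < 0.05
threshold throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ttest_ind

from .errors import AnalysisError, InputError
from .matrix import OmicsMatrix

__all__ = [
    "dep_call",
    "deps_all_transitions",
    "attribute_changes",
    "fgo_originated",
    "chx_response",
    "overlap_enrichment",
    "dormant_mrna_set",
]


def _ttest_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise equal-variance two-tailed t-test p-values with the
    zero-variance convention: if both groups are constant, p = 1 when the
    means are equal and p = 0 otherwise."""
    p = ttest_ind(a, b, axis=1, equal_var=True).pvalue
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return p


def dep_call(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    transition: str = "",
    layer: str = "",
) -> pd.DataFrame:
    """Differential calls between two replicate groups of log2 values.

    ``log2_fc`` = mean(B) - mean(A).  Direction is "up"/"down" when
    |log2_fc| >= ``fc_threshold`` (1.0 = two-fold) and p < ``p_threshold``,
    else "none".  Genes with fewer than two detected replicates in either
    group are skipped (``tested`` False, direction "none").
    """
    shared = group_a.index.intersection(group_b.index)
    a = group_a.loc[shared].to_numpy(dtype=float)
    b = group_b.loc[shared].to_numpy(dtype=float)
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    log2_fc = np.full(len(shared), np.nan)
    p = np.full(len(shared), np.nan)
    if testable.any():
        # complete-case within testable rows; replicate counts are uniform
        # per group in this design, so finite rows are rectangular
        at = np.where(np.isfinite(a[testable]), a[testable], np.nan)
        bt = np.where(np.isfinite(b[testable]), b[testable], np.nan)
        mean_a = np.nanmean(at, axis=1)
        mean_b = np.nanmean(bt, axis=1)
        log2_fc[testable] = mean_b - mean_a
        # t-test needs rectangular arrays: drop NaN columns per row by
        # falling back to a python loop only for ragged rows
        rect = (
            np.isfinite(a[testable]).all(axis=1)
            & np.isfinite(b[testable]).all(axis=1)
        )
        idx_testable = np.where(testable)[0]
        if rect.any():
            rows = idx_testable[rect]
            p[rows] = _ttest_rows(a[rows], b[rows])
        for row in idx_testable[~rect]:
            xa = a[row][np.isfinite(a[row])]
            xb = b[row][np.isfinite(b[row])]
            p[row] = _ttest_rows(xa[None, :], xb[None, :])[0]

    direction = np.where(
        testable & (np.abs(log2_fc) >= fc_threshold) & (p < p_threshold),
        np.where(log2_fc > 0, "up", "down"),
        "none",
    )
    return pd.DataFrame(
        {
            "transition": transition,
            "layer": layer,
            "log2_fc": log2_fc,
            "p_value": p,
            "direction": direction,
            "tested": testable,
        },
        index=shared,
    )


def deps_all_transitions(
    matrix: OmicsMatrix,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    log_fpkm_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """DEP/DEG calls for every consecutive stage transition of a
    replicate-level matrix (FPKM layers are log2(x + pseudocount) first)."""
    if matrix.is_stage_averaged:
        raise InputError("deps_all_transitions needs replicate-level data")
    log_vals = matrix.log_values(pseudocount=log_fpkm_pseudocount)
    stages = matrix.stages_present
    tables = []
    for s_a, s_b in zip(stages[:-1], stages[1:]):
        ga = log_vals[matrix.columns_for_stage(s_a)]
        gb = log_vals[matrix.columns_for_stage(s_b)]
        tables.append(
            dep_call(
                ga, gb, fc_threshold, p_threshold,
                transition=f"{s_a}->{s_b}", layer=matrix.layer,
            )
        )
    return pd.concat(tables)


def attribute_changes(
    deps: pd.DataFrame,
    rpf_changes: pd.DataFrame,
    mrna_changes: pd.DataFrame,
    lag: int = 2,
    change_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute each protein DEP to mRNA, RPF-only, or neither.

    For a DEP at transition i, the mRNA (then RPF) change tables are
    scanned over transitions i, i-1, ..., i-``lag``: a same-sign log2
    change with absolute value > ``change_threshold`` (two-fold) in the
    window assigns "mrna_contributed", else "rpf_only", else
    "unexplained".  Returns (per-DEP categories, per-transition fractions).
    """
    transitions = list(rpf_changes.columns)
    if list(mrna_changes.columns) != transitions:
        raise AnalysisError("RPF and mRNA change tables must share transitions")
    called = deps[deps["direction"].isin(["up", "down"])]
    missing = set(called["transition"]) - set(transitions)
    if missing:
        raise AnalysisError(f"transition(s) missing from change tables: {sorted(missing)}")

    rows = []
    for gene, dep in called.iterrows():
        t_idx = transitions.index(dep["transition"])
        window = transitions[max(0, t_idx - lag) : t_idx + 1]
        sign = 1.0 if dep["direction"] == "up" else -1.0

        def supported(changes: pd.DataFrame) -> bool:
            if gene not in changes.index:
                return False
            w = changes.loc[gene, window]
            return bool(((w * sign) > change_threshold).any())

        if supported(mrna_changes):
            category = "mrna_contributed"
        elif supported(rpf_changes):
            category = "rpf_only"
        else:
            category = "unexplained"
        rows.append(
            {
                "gene_id": gene,
                "transition": dep["transition"],
                "direction": dep["direction"],
                "category": category,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        fractions = (
            table.groupby("transition")["category"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
    else:
        fractions = pd.DataFrame()
    return table, fractions


def fgo_originated(
    protein: OmicsMatrix,
    rpf: OmicsMatrix,
    fpkm_threshold: float = 5.0,
    from_stage: str = "1C",
) -> tuple[pd.Index, float]:
    """Oocyte-stockpiled proteins with negligible embryonic translation.

    Returns genes detected in the FGO proteome whose RPF FPKM stays below
    ``fpkm_threshold`` at every stage from ``from_stage`` onward, together
    with the fraction of them still detected (protein non-missing) at the
    final stage — the blastocyst persistence.
    """
    if not (protein.is_stage_averaged and rpf.is_stage_averaged):
        raise InputError("fgo_originated expects stage-averaged matrices")
    shared = protein.genes.intersection(rpf.genes)
    stages = list(rpf.values.columns)
    post = stages[stages.index(from_stage) :]
    fgo_detected = protein.values.loc[shared, "FGO"].notna()
    low_rpf = (rpf.values.loc[shared, post].fillna(0) < fpkm_threshold).all(axis=1)
    genes = shared[fgo_detected & low_rpf]
    last_stage = protein.values.columns[-1]
    persistence = (
        float(protein.values.loc[genes, last_stage].notna().mean()) if len(genes) else np.nan
    )
    return genes, persistence


def chx_response(
    dmso: pd.DataFrame,
    chx: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Translation-inhibition response in MII oocytes.

    ``chx`` may pool the 24 h and 48 h treatment replicates.  Repressed =
    down in CHX versus DMSO by the differential rule with the four-fold
    threshold (|log2 fc| >= 2); unaffected = the remaining tested genes.
    """
    calls = dep_call(dmso, chx, fc_threshold=fc_threshold, p_threshold=p_threshold)
    tested = calls[calls["tested"]]
    repressed = set(tested.index[tested["direction"] == "down"])
    unaffected = set(tested.index) - repressed
    return repressed, unaffected


@dataclass(frozen=True)
class OverlapResult:
    odds_ratio: float
    p_value: float
    overlap: int
    overlap_fraction_a: float
    table: tuple[tuple[int, int], tuple[int, int]]


def overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Two-sided Fisher's exact test for the overlap of two gene sets."""
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = ((n11, n10), (n01, n00))
    odds, p = fisher_exact(table, alternative="two-sided")
    return OverlapResult(
        odds_ratio=float(odds),
        p_value=float(p),
        overlap=n11,
        overlap_fraction_a=n11 / len(a) if a else np.nan,
        table=table,
    )


def dormant_mrna_set(
    rpf: OmicsMatrix,
    mrna: OmicsMatrix,
    ratio: float = 2.0,
    pseudocount: float = 0.1,
) -> pd.Index:
    """Maternal transcripts translationally activated at meiotic resumption.

    Dormant mRNAs gain translation without gaining transcript: RPF
    MII/FGO ratio > ``ratio`` while mRNA MII/FGO ratio < ``ratio``
    (ratios on FPKM with a pseudocount against division by zero).
    """
    if not (rpf.is_stage_averaged and mrna.is_stage_averaged):
        raise InputError("dormant_mrna_set expects stage-averaged matrices")
    shared = rpf.genes.intersection(mrna.genes)
    rv = rpf.values.loc[shared].fillna(0)
    mv = mrna.values.loc[shared].fillna(0)
    rpf_ratio = (rv["MII"] + pseudocount) / (rv["FGO"] + pseudocount)
    mrna_ratio = (mv["MII"] + pseudocount) / (mv["FGO"] + pseudocount)
    return shared[(rpf_ratio > ratio) & (mrna_ratio < ratio)]
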