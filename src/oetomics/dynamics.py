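"""Dynamic-vs-stable calls, trajectory clustering, and stage correlation.

A gene counts as dynamically expressed in a layer if the coefficient of
variation (sample sd / mean) of its log2 values across stages exceeds 0.2.
Protein trajectories are clustered with Euclidean K-means (k = 10, best of
100 restarts) on per-gene z-scored profiles, after which embryonic
clusters appearing at different post-ZGA stages can be merged into one
group.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .errors import AnalysisError, ConfigError, InputError
from .matrix import FPKM_LAYERS, OmicsMatrix

__all__ = [
    "coefficient_of_variation",
    "classify_dynamics",
    "cluster_trajectories",
    "merge_to_groups",
    "embryonic_merge_mapping",
    "stage_correlation_matrix",
]


def coefficient_of_variation(series: np.ndarray | pd.Series) -> float:
    """Sample CV = sd(n-1) / mean; requires >= 2 values and positive mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise AnalysisError("CV needs at least two stages")
    mean = x.mean()
    if mean <= 0:
        raise AnalysisError(f"CV undefined for nonpositive mean ({mean})")
    return float(x.std(ddof=1) / mean)


def classify_dynamics(
    matrix: OmicsMatrix,
    threshold: float = 0.2,
    min_fpkm: float = 1.0,
    impute_shift: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Per-gene dynamic/stable calls on a stage-averaged matrix.

    For FPKM layers only genes expressed (FPKM >= ``min_fpkm``) at one or
    more stages are eligible, and the CV is taken on log2(FPKM + 1).  For
    the protein layer all genes are eligible and missing stages are imputed
    just below the detected minimum.  Returns (calls, dynamic fraction).
    """
    if not matrix.is_stage_averaged:
        raise InputError("classify_dynamics expects a stage-averaged matrix")
    if matrix.layer in FPKM_LAYERS:
        eligible = (matrix.values.fillna(0) >= min_fpkm).any(axis=1)
        log_vals = matrix.log_values()
    else:
        eligible = pd.Series(True, index=matrix.genes)
        log_vals = matrix.imputed(shift=impute_shift)
    log_vals = log_vals[eligible]
    if log_vals.empty:
        raise AnalysisError("no eligible genes")
    cv = log_vals.apply(coefficient_of_variation, axis=1)
    calls = pd.DataFrame(
        {
            "layer": matrix.layer,
            "cv": cv,
            "label": np.where(cv > threshold, "dynamic", "stable"),
        }
    )
    fraction = float((calls["label"] == "dynamic").mean())
    return calls, fraction


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    sd = sd.replace(0.0, 1.0)  # flat trajectories map to all-zero profiles
    return values.sub(mu, axis=0).div(sd, axis=0)


def cluster_trajectories(
    protein: OmicsMatrix,
    k: int = 10,
    restarts: int = 100,
    seed: int = 1,
    impute_shift: float = 1.0,
) -> tuple[pd.DataFrame, float]:
    """Euclidean K-means on z-scored protein trajectories.

    Runs ``restarts`` random initializations and keeps the assignment with
    the lowest within-cluster sum of squares; deterministic given ``seed``.
    Returns (assignments with 1-based ``kmeans_cluster``, best SSE).
    """
    if not protein.is_stage_averaged:
        raise InputError("cluster_trajectories expects a stage-averaged matrix")
    values = protein.imputed(shift=impute_shift)
    if k > len(values):
        raise InputError(f"k={k} exceeds number of genes ({len(values)})")
    z = _zscore_rows(values)
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(z.to_numpy())
    assignments = pd.DataFrame(
        {"kmeans_cluster": km.labels_ + 1}, index=protein.genes
    )
    return assignments, float(km.inertia_)


def merge_to_groups(
    assignments: pd.DataFrame, mapping: Mapping[int, str]
) -> pd.DataFrame:
    """Attach a ``group_label`` column by mapping clusters to named groups."""
    clusters = set(assignments["kmeans_cluster"].unique())
    uncovered = clusters - set(mapping)
    if uncovered:
        raise ConfigError(f"mapping does not cover cluster(s): {sorted(uncovered)}")
    out = assignments.copy()
    out["group_label"] = assignments["kmeans_cluster"].map(mapping)
    return out


def embryonic_merge_mapping(
    assignments: pd.DataFrame,
    protein: OmicsMatrix,
    detection_floor: float,
) -> dict[int, str]:
    """Automated rule merging post-ZGA clusters into one "embryonic" group.

    A cluster is embryonic if its mean trajectory (not imputed; detected
    values only) stays below the detection floor — or is entirely
    undetected — at every pre-ZGA stage (before the 2-cell stage, where
    the major wave of zygotic genome activation produces the first
    embryonic proteins) and its final-stage mean rises above the floor.
    Other clusters keep their numeric identity as ``cluster_<i>``; an
    explicit config mapping can override this rule.
    """
    if not protein.is_stage_averaged:
        raise InputError("expects a stage-averaged matrix")
    stages = list(protein.values.columns)
    pre_zga = stages[: stages.index("2C")] if "2C" in stages else stages[:3]
    mapping: dict[int, str] = {}
    for c in sorted(assignments["kmeans_cluster"].unique()):
        genes = assignments.index[assignments["kmeans_cluster"] == c]
        mean_traj = protein.values.loc[genes].mean(axis=0)
        early = mean_traj[pre_zga]
        early_low = bool(((early < detection_floor) | early.isna()).all())
        late_high = bool(mean_traj.iloc[-1] >= detection_floor)
        mapping[c] = "embryonic" if early_low and late_high else f"cluster_{c}"
    return mapping


def stage_correlation_matrix(
    a: OmicsMatrix,
    b: OmicsMatrix,
    impute_shift: float = 1.0,
) -> pd.DataFrame:
    """Spearman correlation across genes for every stage pair of two layers."""
    if not (a.is_stage_averaged and b.is_stage_averaged):
        raise InputError("stage_correlation_matrix expects stage-averaged matrices")
    shared = a.genes.intersection(b.genes)
    if len(shared) < 3:
        raise AnalysisError("fewer than 3 shared genes")
    av = a.imputed(shift=impute_shift).loc[shared]
    bv = b.imputed(shift=impute_shift).loc[shared]
    out = pd.DataFrame(
        index=pd.Index(av.columns, name=a.layer),
        columns=pd.Index(bv.columns, name=b.layer),
        dtype=float,
    )
    for si in av.columns:
        for sj in bv.columns:
            out.loc[si, sj] = spearmanr(av[si], bv[sj]).statistic
    return out
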