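"""Allele-resolved protein analysis.

Crosses of divergent mouse strains (maternal C57BL/6J x paternal PWK/PhJ)
make parental alleles distinguishable at nonsynonymous variant sites.  For
the MS search, each variant is represented by a 61-amino-acid window (30
residues each side of the variant, clipped at protein termini) in both the
reference and alternate form.  Allele-specific expression (ASE) is called
per stage by an equal-variance two-tailed t-test between maternal and
paternal replicate intensities with a two-fold change requirement; a gene
shows ASE if the rule holds at any embryo stage (1C..BL), with
single-allele detection (the other allele entirely missing) also counting.

Category assignment is an operationalization of the descriptive patterns
used for parent-of-origin heat maps:

* ``oocyte_specific`` — detected in oocytes, paternal allele never seen;
* ``oocyte_embryonic`` — maternal-only early embryo signal with the
  paternal allele appearing at a later embryo stage;
* ``embryonic_maternal`` / ``embryonic_paternal`` — detection confined to
  embryo stages with only one allele ever detected;
* ``none`` — everything else (including balanced biallelic genes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .errors import InputError
from .stages import DEFAULT_SERIES, EMBRYO_STAGES, StageSeries

__all__ = ["extract_variant_peptide", "ase_call"]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def extract_variant_peptide(
    sequence: str,
    position: int,
    alt_residue: str,
    flank: int = 30,
) -> tuple[str, str]:
    """Variant-centred (reference, alternate) peptide windows.

    The window spans ``flank`` residues each side of the 1-based variant
    ``position`` (61 aa for the default flank), clipped at the protein
    termini rather than padded.  The alternate window substitutes the
    variant residue; it must differ from the reference residue.
    """
    if not 1 <= position <= len(sequence):
        raise InputError(
            f"position {position} outside protein of length {len(sequence)}"
        )
    alt = alt_residue.upper()
    if alt not in STANDARD_AA:
        raise InputError(f"not a standard amino acid: {alt_residue!r}")
    ref = sequence[position - 1]
    if alt == ref:
        raise InputError(f"synonymous variant at position {position} ({ref})")
    start = max(0, position - 1 - flank)
    end = min(len(sequence), position + flank)
    ref_window = sequence[start:end]
    offset = position - 1 - start
    alt_window = ref_window[:offset] + alt + ref_window[offset + 1 :]
    return ref_window, alt_window


def _stage_test(mat: np.ndarray, pat: np.ndarray) -> tuple[float, float]:
    """(log2_fc maternal - paternal, p) with missing-allele and
    zero-variance conventions.

    A stage where one allele is detected (>= 2 replicates) and the other is
    entirely missing is an infinite fold change with p = 0 (detection
    itself is the evidence).  If both groups are constant: p = 1 for equal
    means, 0 otherwise.
    """
    mat = mat[np.isfinite(mat)]
    pat = pat[np.isfinite(pat)]
    if len(mat) >= 2 and len(pat) == 0:
        return np.inf, 0.0
    if len(pat) >= 2 and len(mat) == 0:
        return -np.inf, 0.0
    if len(mat) < 2 or len(pat) < 2:
        return np.nan, np.nan
    fc = float(mat.mean() - pat.mean())
    if mat.var(ddof=1) == 0 and pat.var(ddof=1) == 0:
        return fc, (1.0 if np.isclose(mat.mean(), pat.mean()) else 0.0)
    return fc, float(ttest_ind(mat, pat, equal_var=True).pvalue)


def ase_call(
    table: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    series: StageSeries = DEFAULT_SERIES,
    embryo_stages: tuple[str, ...] = EMBRYO_STAGES,
) -> pd.DataFrame:
    """Per-gene ASE calls and category from an allele intensity table.

    ``table`` is long-form with columns gene_id, stage, replicate,
    maternal, paternal (log2 intensities, NaN = not detected).  Returns one
    row per gene: per-stage log2 fold changes and p-values (as dicts),
    the ASE flag, and the detection-pattern category.
    """
    required = {"gene_id", "stage", "replicate", "maternal", "paternal"}
    if not required <= set(table.columns):
        raise InputError(f"allele table must have columns {sorted(required)}")
    oocyte_stages = tuple(s for s in series.labels if s not in embryo_stages)
    post_zga = tuple(s for s in embryo_stages if s != "1C")

    rows = []
    for gene, sub in table.groupby("gene_id", sort=True):
        fc_by_stage: dict[str, float] = {}
        p_by_stage: dict[str, float] = {}
        mat_det: dict[str, bool] = {}
        pat_det: dict[str, bool] = {}
        for stage in series.labels:
            grp = sub[sub["stage"] == stage]
            if grp.empty:
                continue
            mat = grp["maternal"].to_numpy(dtype=float)
            pat = grp["paternal"].to_numpy(dtype=float)
            mat_det[stage] = bool(np.isfinite(mat).any())
            pat_det[stage] = bool(np.isfinite(pat).any())
            fc, p = _stage_test(mat, pat)
            fc_by_stage[stage] = fc
            p_by_stage[stage] = p

        def significant(stage: str) -> bool:
            fc, p = fc_by_stage.get(stage, np.nan), p_by_stage.get(stage, np.nan)
            return bool(np.isfinite(p) and p < p_threshold and abs(fc) > fc_threshold)

        ase = any(significant(s) for s in embryo_stages)

        oocyte_detected = any(mat_det.get(s) or pat_det.get(s) for s in oocyte_stages)
        pat_ever = any(pat_det.get(s, False) for s in series.labels)
        mat_ever = any(mat_det.get(s, False) for s in series.labels)
        mat_only_embryo = [
            s for s in embryo_stages if mat_det.get(s) and not pat_det.get(s)
        ]
        category = "none"
        if oocyte_detected and mat_ever and not pat_ever:
            category = "oocyte_specific"
        elif oocyte_detected and mat_only_embryo and any(
            pat_det.get(s, False) for s in embryo_stages
        ):
            category = "oocyte_embryonic"
        elif not oocyte_detected and (mat_ever != pat_ever):
            category = "embryonic_maternal" if mat_ever else "embryonic_paternal"
        rows.append(
            {
                "gene_id": gene,
                "ase": ase,
                "category": category,
                "log2_fc_by_stage": fc_by_stage,
                "p_by_stage": p_by_stage,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
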