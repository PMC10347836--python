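"""Reading and writing the pipeline's plain-text formats.

Matrix dialect: tab-separated, genes as rows (first column ``gene_id``),
sample columns named ``STAGE_repN``; an empty cell means "not detected".
Disorder scores: one line per gene, the gene id followed by
whitespace-separated per-residue scores.  Variant peptide windows are
written as FASTA with headers ``gene_id|pos|allele``.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .matrix import FPKM_LAYERS, OmicsMatrix, sample_meta
from .stages import DEFAULT_SERIES, StageSeries

__all__ = [
    "load_matrix",
    "write_matrix",
    "read_disorder_scores",
    "write_disorder_scores",
    "write_idr_segments",
    "write_variant_windows",
    "write_bundle",
    "config_to_yaml",
    "config_from_yaml",
]

_COLUMN_RE = re.compile(r"^(?P<stage>.+)_rep(?P<rep>\d+)$")


def _parse_columns(
    columns: list[str],
    stage_map: Mapping[str, tuple] | None,
    series: StageSeries,
) -> pd.DataFrame:
    """Column metadata from an explicit map or the STAGE_repN convention.

    ``stage_map`` values are (stage, replicate) or (stage, replicate, batch).
    """
    stages, reps, batches = [], [], []
    for col in columns:
        if stage_map is not None:
            if col not in stage_map:
                raise InputError(f"column {col!r} not in stage_map")
            entry = tuple(stage_map[col])
            stage, rep = entry[0], entry[1]
            batch = entry[2] if len(entry) > 2 else None
        else:
            m = _COLUMN_RE.match(col)
            if not m:
                raise InputError(f"cannot parse column name {col!r}; provide stage_map")
            stage, rep, batch = m.group("stage"), int(m.group("rep")), None
        if stage not in series.labels:
            raise InputError(f"unknown stage label {stage!r} in column {col!r}")
        stages.append(stage)
        reps.append(rep)
        batches.append(batch)
    return sample_meta(stages, reps, batches, names=columns)


def load_matrix(
    path: str | Path,
    layer: str,
    stage_map: Mapping[str, tuple] | None = None,
    series: StageSeries = DEFAULT_SERIES,
) -> OmicsMatrix:
    """Load a gene x sample TSV as an :class:`OmicsMatrix`.

    Empty cells are missing.  On the protein layer, explicit zero
    intensities are also treated as not detected; FPKM layers keep zeros
    as detected values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate gene ids in {path}: {dups[:5]}")
    meta = _parse_columns(list(df.columns), stage_map, series)
    values = df.astype(float)
    if layer not in FPKM_LAYERS:
        values = values.where(values != 0.0)
    return OmicsMatrix(layer, values, meta, series)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`load_matrix` (empty cell = missing)."""
    matrix.values.to_csv(path, sep="\t", na_rep="")


def read_disorder_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Per-gene per-residue disorder scores (gene id, then floats)."""
    scores: dict[str, np.ndarray] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        scores[parts[0]] = np.array([float(x) for x in parts[1:]])
    return scores


def write_disorder_scores(scores: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, vec in scores.items():
            fh.write(gene + " " + " ".join(f"{v:.4f}" for v in vec) + "\n")


def write_idr_segments(segments: Mapping[str, list], path: str | Path) -> None:
    """BED-like TSV of IDR segments.

    Coordinates follow BED convention (0-based start, half-open end);
    the in-memory segments are 1-based inclusive, so start-1 is written.
    """
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\n")
        for gene, segs in segments.items():
            for seg in segs:
                fh.write(f"{gene}\t{seg.start - 1}\t{seg.end}\n")


def write_variant_windows(
    windows: list[tuple[str, int, str, str]], path: str | Path, width: int = 60
) -> None:
    """FASTA of variant peptide windows; entries are (gene_id, pos, allele, seq)."""
    with open(path, "w") as fh:
        for gene, pos, allele, seq in windows:
            fh.write(f">{gene}|{pos}|{allele}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bundle(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic bundle as the pipeline's input files.

    Produces protein/rpf/mrna matrices, the allele table, disorder scores,
    the per-gene truth report, and the generator config as YAML.  Returns
    the paths written.  The protein column -> batch assignment is stored in
    the config file rather than the matrix itself.
    """
    from .simulate import truth_report  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein": outdir / "protein_log2_ibaq.tsv",
        "rpf": outdir / "rpf_fpkm.tsv",
        "mrna": outdir / "mrna_fpkm.tsv",
        "allele": outdir / "allele_intensity.tsv",
        "disorder": outdir / "disorder_scores.txt",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_matrix(bundle.protein, paths["protein"])
    write_matrix(bundle.rpf, paths["rpf"])
    write_matrix(bundle.mrna, paths["mrna"])
    bundle.allele.to_csv(paths["allele"], sep="\t", index=False, na_rep="")
    write_disorder_scores(bundle.disorder, paths["disorder"])
    truth_report(bundle).to_csv(paths["truth"], sep="\t")
    config_to_yaml(bundle.config, bundle.protein.meta, paths["config"])
    return paths


def config_to_yaml(config, protein_meta: pd.DataFrame, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["batch_offsets"] = {int(k): float(v) for k, v in payload["batch_offsets"].items()}
    payload["stage_map"] = {
        name: [row["stage"], int(row["replicate"]), int(row["batch"])]
        for name, row in protein_meta.iterrows()
    }
    if payload.get("stage_times") is not None:
        payload["stage_times"] = [float(t) for t in payload["stage_times"]]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path: str | Path):
    """Load generator settings (and the protein stage_map) back from YAML."""
    from .simulate import GeneratorConfig

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    stage_map = {k: tuple(v) for k, v in payload.pop("stage_map", {}).items()}
    if payload.get("stage_times") is not None:
        payload["stage_times"] = tuple(payload["stage_times"])
    config = GeneratorConfig(**payload)
    return config, stage_map
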