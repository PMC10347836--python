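"""Synthetic multi-omics bundles with known ground truth.

The generator emulates the statistical structure of a stage-resolved
oocyte-to-embryo transition (OET) study: seven ordered stages (FGO .. BL),
a proteome measured in three batches with replicate structure matching the
study design (FGO in every batch, four FGO replicates, blastocysts in the
third batch), and matched translatome (RPF FPKM) and transcriptome (mRNA
FPKM) layers with two replicates each.

Genes are drawn from trajectory classes mirroring the groups seen in
protein K-means clustering of such data:

* four "constitutive" subgroups — stable protein, with RPF that is itself
  constitutive, OET-downregulated, uniformly low, or maternal-decaying;
* "maternal" — abundant oocyte protein degraded over development;
* "oet_down" / "oet_up" — proteins falling or rising upon meiotic
  resumption (the up class is driven by dormant mRNAs: translation rises
  from FGO to MII with flat mRNA);
* "embryonic" — absent before zygotic genome activation, produced after;
* "low" — below the detection floor throughout.

Each gene carries kinetic parameters (p0, alpha, kd); its noiseless protein
trajectory is forward-simulated from its own RPF template through
:mod:`oetomics.kinetics`, so downstream kinetic fitting has an exact truth
to recover.  Measurement realism comes from (i) per-replicate lognormal
noise, (ii) additive per-batch log2 offsets on the protein layer, and
(iii) an intensity detection floor below which protein values are masked
missing.  One pseudo-random stream per layer is split from the master seed
so layers can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .kinetics import RpfTrajectory, simulate_protein
from .matrix import OmicsMatrix, sample_meta
from .stages import DEFAULT_SERIES, StageSeries

__all__ = [
    "GeneratorConfig",
    "GeneTruth",
    "SyntheticBundle",
    "generate_bundle",
    "truth_report",
    "generate_chx_experiment",
]

GENE_CLASSES = (
    "constitutive_rpf_constitutive",
    "constitutive_rpf_oet_down",
    "constitutive_rpf_low",
    "constitutive_rpf_maternal",
    "maternal",
    "oet_down",
    "oet_up",
    "embryonic",
    "low",
)

ASE_CATEGORIES = (
    "none",
    "oocyte_specific",
    "oocyte_embryonic",
    "embryonic_maternal",
    "embryonic_paternal",
)


@dataclass(frozen=True)
class ClassSpec:
    """Trajectory archetype: kinetic parameters plus per-stage FPKM templates."""

    p0_log2: float
    alpha: float
    kd: float
    rpf: tuple[float, ...]
    mrna: tuple[float, ...]


# Defaults chosen so that, with stage times 0..6 and a detection floor of
# 6.0 log2 units: the four constitutive subgroups have log2-protein CV well
# below 0.2 (stable); maternal / oet_down / oet_up / embryonic exceed it
# (dynamic); embryonic protein is below the floor before the 2-cell stage;
# oet_up genes are "dormant" (RPF MII/FGO > 2 with flat mRNA); and
# constitutive_rpf_low genes are FGO-originated (RPF < 5 from 1C onward).
CLASS_SPECS: Mapping[str, ClassSpec] = {
    "constitutive_rpf_constitutive": ClassSpec(
        11.0, 20.0, 0.30, (30, 30, 30, 30, 30, 30, 30), (30, 28, 26, 24, 22, 24, 26)
    ),
    "constitutive_rpf_oet_down": ClassSpec(
        11.5, 2.0, 0.05, (60, 60, 25, 10, 5, 5, 5), (40, 35, 15, 8, 6, 8, 10)
    ),
    "constitutive_rpf_low": ClassSpec(
        11.0, 1.0, 0.03, (2, 2, 2, 2, 2, 2, 2), (8, 7, 6, 5, 4, 4, 5)
    ),
    "constitutive_rpf_maternal": ClassSpec(
        11.0, 3.0, 0.08, (50, 40, 20, 8, 3, 2, 2), (40, 30, 15, 6, 3, 2, 2)
    ),
    "maternal": ClassSpec(
        12.0, 0.5, 0.90, (40, 30, 10, 4, 2, 1, 1), (50, 35, 15, 5, 2, 1, 1)
    ),
    "oet_down": ClassSpec(
        11.5, 1.0, 1.20, (50, 10, 5, 3, 2, 2, 2), (45, 15, 8, 4, 3, 3, 3)
    ),
    "oet_up": ClassSpec(
        5.0, 25.0, 0.25, (5, 30, 40, 40, 30, 25, 20), (30, 30, 25, 20, 15, 12, 10)
    ),
    "embryonic": ClassSpec(
        0.0, 30.0, 0.20, (0.3, 0.3, 1, 10, 30, 50, 70), (0.3, 0.3, 0.5, 15, 40, 60, 80)
    ),
    "low": ClassSpec(
        3.0, 0.05, 0.10, (0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5), (0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    ),
}

DEFAULT_PROPORTIONS: Mapping[str, float] = {
    "constitutive_rpf_constitutive": 0.20,
    "constitutive_rpf_oet_down": 0.10,
    "constitutive_rpf_low": 0.09,
    "constitutive_rpf_maternal": 0.09,
    "maternal": 0.12,
    "oet_down": 0.08,
    "oet_up": 0.08,
    "embryonic": 0.16,
    "low": 0.08,
}

DEFAULT_BATCH_OFFSETS: Mapping[int, float] = {1: 0.0, 2: 0.7, 3: -0.4}

DEFAULT_ASE_PROPORTIONS: Mapping[str, float] = {
    "none": 0.50,
    "oocyte_specific": 0.20,
    "oocyte_embryonic": 0.15,
    "embryonic_maternal": 0.10,
    "embryonic_paternal": 0.05,
}


@dataclass
class GeneratorConfig:
    """Settings for :func:`generate_bundle`.

    ``noise_sd`` is the per-replicate measurement noise in log2 units
    (lognormal on the linear scale) applied to every layer;
    ``gene_jitter_sd`` spreads per-gene parameters around their class
    archetype (also log2 units) and is part of the ground truth, not noise.
    """

    n_genes: int = 400
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    noise_sd: float = 0.1
    gene_jitter_sd: float = 0.3
    batch_offsets: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BATCH_OFFSETS)
    )
    detection_floor: float = 6.0
    n_zero_rna: int = 0
    allele_fraction: float = 0.15
    ase_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASE_PROPORTIONS)
    )
    seed: int = 0
    stage_times: tuple[float, ...] | None = None

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown gene class(es): {sorted(unknown)}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigError("class proportions must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.gene_jitter_sd < 0:
            raise ConfigError("gene_jitter_sd must be nonnegative")
        if not 0 <= self.allele_fraction <= 1:
            raise ConfigError("allele_fraction must be in [0, 1]")
        if self.n_zero_rna < 0 or self.n_zero_rna > self.n_genes:
            raise ConfigError("n_zero_rna must be in [0, n_genes]")
        total_ase = sum(self.ase_proportions.values())
        if abs(total_ase - 1.0) > 1e-9:
            raise ConfigError("ase proportions must sum to 1")


@dataclass
class GeneTruth:
    """Ground truth for one synthetic gene."""

    gene_id: str
    class_label: str
    p0: float
    alpha: float
    kd: float
    rpf_template: np.ndarray
    mrna_template: np.ndarray
    rna_all_zero: bool = False
    ase_category: str | None = None
    has_idr: bool = False
    idr_segment: tuple[int, int] | None = None


@dataclass
class SyntheticBundle:
    """Everything a downstream test needs: data layers plus per-gene truth."""

    protein: OmicsMatrix
    rpf: OmicsMatrix
    mrna: OmicsMatrix
    allele: pd.DataFrame
    disorder: dict[str, np.ndarray]
    truth: list[GeneTruth]
    config: GeneratorConfig
    series: StageSeries
    #: noiseless, batch-free log2 protein stage matrix (floor applied)
    protein_truth_log2: pd.DataFrame


# -- helpers ---------------------------------------------------------------

def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment: class counts within +-1 of n*p."""
    keys = [k for k in GENE_CLASSES if k in proportions]
    raw = np.array([n * proportions[k] for k in keys])
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for i in np.argsort(-remainder)[:short]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _protein_sample_meta(series: StageSeries) -> pd.DataFrame:
    """Study-design proteome columns: FGO x4 across 3 batches, BL in batch 3."""
    stages, reps, batches = [], [], []
    for s in series.labels:
        if s == "FGO":
            for r, b in [(1, 1), (2, 2), (3, 3), (4, 3)]:
                stages.append(s), reps.append(r), batches.append(b)
        elif s == "BL":
            for r in (1, 2):
                stages.append(s), reps.append(r), batches.append(3)
        else:
            for r, b in [(1, 1), (2, 2)]:
                stages.append(s), reps.append(r), batches.append(b)
    return sample_meta(stages, reps, batches)


def _noiseless_log2_traj(truth: GeneTruth, series: StageSeries) -> np.ndarray:
    traj = RpfTrajectory(np.asarray(series.times), truth.rpf_template)
    p = simulate_protein(truth.p0, truth.alpha, truth.kd, traj)
    with np.errstate(divide="ignore"):
        return np.log2(np.maximum(p, 0.0))


# -- main entry points ------------------------------------------------------

def generate_bundle(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a complete synthetic input bundle; deterministic given the seed."""
    config.validate()
    series = (
        DEFAULT_SERIES
        if config.stage_times is None
        else StageSeries(DEFAULT_SERIES.labels, config.stage_times)
    )
    n_stages = len(series)
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_prot, rng_rpf, rng_mrna, rng_allele, rng_idr = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # ----- per-gene truth
    counts = _allocate_counts(config.n_genes, config.class_proportions)
    truths: list[GeneTruth] = []
    i = 0
    for cls in GENE_CLASSES:
        for _ in range(counts.get(cls, 0)):
            spec = CLASS_SPECS[cls]
            jit = lambda: 2.0 ** rng_truth.normal(0.0, config.gene_jitter_sd)
            p0 = (2.0 ** spec.p0_log2) * jit() if spec.p0_log2 > 0 else 0.0
            alpha = spec.alpha * jit()
            kd = spec.kd * jit()
            scale_rna = jit()
            truths.append(
                GeneTruth(
                    gene_id=f"G{i:05d}",
                    class_label=cls,
                    p0=p0,
                    alpha=alpha,
                    kd=kd,
                    rpf_template=np.asarray(spec.rpf, dtype=float) * scale_rna,
                    mrna_template=np.asarray(spec.mrna, dtype=float) * scale_rna,
                )
            )
            i += 1
    if config.n_zero_rna:
        for t in rng_truth.choice(truths, size=config.n_zero_rna, replace=False):
            t.rna_all_zero = True
            t.rpf_template = np.zeros(n_stages)
            t.mrna_template = np.zeros(n_stages)
    genes = pd.Index([t.gene_id for t in truths], name="gene_id")

    # ----- noiseless protein truth (log2, floored)
    log2_traj = np.vstack([_noiseless_log2_traj(t, series) for t in truths])
    truth_log2 = pd.DataFrame(log2_traj, index=genes, columns=list(series.labels))
    truth_log2 = truth_log2.where(truth_log2 >= config.detection_floor)

    # ----- protein replicates with noise, batch offsets, detection floor
    pmeta = _protein_sample_meta(series)
    stage_idx = {s: k for k, s in enumerate(series.labels)}
    cols = {}
    for name, row in pmeta.iterrows():
        noisy = log2_traj[:, stage_idx[row["stage"]]] + (
            rng_prot.normal(0.0, config.noise_sd, size=len(genes))
            if config.noise_sd > 0
            else 0.0
        )
        detected = noisy >= config.detection_floor
        vals = noisy + config.batch_offsets.get(row["batch"], 0.0)
        cols[name] = np.where(detected, vals, np.nan)
    protein = OmicsMatrix(
        "protein_log2_ibaq", pd.DataFrame(cols, index=genes), pmeta, series
    )

    # ----- RNA layers: class-templated FPKM with multiplicative noise
    def rna_layer(layer: str, rng: np.random.Generator, attr: str) -> OmicsMatrix:
        stages = [s for s in series.labels for _ in (1, 2)]
        reps = [r for _ in series.labels for r in (1, 2)]
        meta = sample_meta(stages, reps)
        template = np.vstack([getattr(t, attr) for t in truths])
        data = {}
        for j, name in enumerate(meta.index):
            noise = (
                2.0 ** rng.normal(0.0, config.noise_sd, size=len(genes))
                if config.noise_sd > 0
                else 1.0
            )
            data[name] = template[:, j // 2] * noise
        return OmicsMatrix(layer, pd.DataFrame(data, index=genes), meta, series)

    rpf = rna_layer("rpf_fpkm", rng_rpf, "rpf_template")
    mrna = rna_layer("mrna_fpkm", rng_mrna, "mrna_template")

    # ----- allele-resolved subset
    allele = _generate_allele_table(
        truths, log2_traj, series, config, rng_allele
    )

    # ----- per-residue disorder scores with planted IDRs in half the genes
    disorder = _generate_disorder(truths, rng_idr)

    return SyntheticBundle(
        protein=protein,
        rpf=rpf,
        mrna=mrna,
        allele=allele,
        disorder=disorder,
        truth=truths,
        config=config,
        series=series,
        protein_truth_log2=truth_log2,
    )


def _generate_allele_table(truths, log2_traj, series, config, rng):
    """Allele-resolved intensities for a subset of genes.

    Only constitutive-class genes are eligible: their protein is detected
    at every stage, so every planted parent-of-origin category (oocyte
    detection, early maternal-only embryo signal, late paternal
    appearance) is actually realizable in the data.
    """
    eligible = [
        i for i, t in enumerate(truths) if t.class_label.startswith("constitutive")
    ]
    n_allele = min(int(round(config.allele_fraction * len(truths))), len(eligible))
    if n_allele == 0:
        return pd.DataFrame(
            columns=["gene_id", "stage", "replicate", "maternal", "paternal"]
        )
    chosen = rng.choice(eligible, size=n_allele, replace=False)
    cats = list(config.ase_proportions)
    cat_counts = _ase_allocate(n_allele, config.ase_proportions)
    assigned = [c for c in cats for _ in range(cat_counts[c])]
    floor = config.detection_floor
    post_zga = {"2C", "4C", "8C", "BL"}
    oocyte = {"FGO", "MII"}
    rows = []
    for gi, cat in zip(chosen, assigned):
        t = truths[gi]
        t.ase_category = cat
        base = log2_traj[gi] - 1.0  # half the total signal per allele
        for k, stage in enumerate(series.labels):
            for rep in (1, 2):
                eps = rng.normal(0.0, config.noise_sd, size=2) if config.noise_sd else (0.0, 0.0)
                mat, pat = base[k] + eps[0], base[k] + eps[1]
                if cat == "oocyte_specific":
                    pat = -np.inf
                elif cat == "oocyte_embryonic":
                    if stage not in ("4C", "8C", "BL"):
                        pat = -np.inf
                elif cat == "embryonic_maternal":
                    if stage in oocyte:
                        mat = -np.inf
                    pat = -np.inf
                elif cat == "embryonic_paternal":
                    if stage in oocyte or stage not in post_zga:
                        mat, pat = -np.inf, -np.inf
                    else:
                        mat = -np.inf
                rows.append(
                    {
                        "gene_id": t.gene_id,
                        "stage": stage,
                        "replicate": rep,
                        "maternal": mat if mat >= floor else np.nan,
                        "paternal": pat if pat >= floor else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _ase_allocate(n, proportions):
    keys = list(proportions)
    raw = np.array([n * proportions[k] for k in keys])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts))


def _generate_disorder(truths, rng):
    """Uniform background scores < 0.5; planted >30-residue disordered run in half."""
    disorder = {}
    for j, t in enumerate(truths):
        length = int(rng.integers(100, 400))
        scores = rng.uniform(0.0, 0.45, size=length)
        if j % 2 == 0:
            run = int(rng.integers(31, 80))
            start = int(rng.integers(0, length - run))
            scores[start : start + run] = rng.uniform(0.7, 0.95, size=run)
            t.has_idr = True
            t.idr_segment = (start + 1, start + run)  # 1-based inclusive
        disorder[t.gene_id] = scores
    return disorder


def truth_report(bundle: SyntheticBundle) -> pd.DataFrame:
    """One row per gene: class, kinetic parameters and derived truth flags.

    Derived flags are computed from each gene's own sampled parameters (not
    its class label), so they remain exact under per-gene jitter:

    * ``is_dormant`` — RPF MII/FGO ratio > 2 with mRNA MII/FGO ratio < 2
      (pseudocount 0.1, as in the differential module);
    * ``is_fgo_originated`` — noiseless protein detected at FGO and RPF
      template < 5 FPKM from the 1-cell stage onward;
    * ``protein_dynamic`` — CV > 0.2 of the noiseless imputed log2 protein
      trajectory, the ground truth for the dynamics classifier at zero noise.
    """
    series = bundle.series
    floor = bundle.config.detection_floor
    tl = bundle.protein_truth_log2
    impute_value = np.nanmin(tl.to_numpy()) - 1.0 if tl.notna().any().any() else 0.0
    imputed = tl.fillna(impute_value)
    sd = imputed.std(axis=1, ddof=1)
    mean = imputed.mean(axis=1)
    cv = sd / mean
    i_1c = series.index("1C")
    pc = 0.1
    rows = []
    for t in bundle.truth:
        r, m = t.rpf_template, t.mrna_template
        dormant = (r[1] + pc) / (r[0] + pc) > 2 and (m[1] + pc) / (m[0] + pc) < 2
        fgo_det = tl.loc[t.gene_id, "FGO"] == tl.loc[t.gene_id, "FGO"]  # not NaN
        fgo_orig = bool(fgo_det and np.all(r[i_1c:] < 5))
        rows.append(
            {
                "gene_id": t.gene_id,
                "class_label": t.class_label,
                "p0": t.p0,
                "alpha": t.alpha,
                "kd": t.kd,
                "rna_all_zero": t.rna_all_zero,
                "is_dormant": bool(dormant and not t.rna_all_zero),
                "is_fgo_originated": fgo_orig,
                "protein_dynamic": bool(cv.loc[t.gene_id] > 0.2),
                "ase_category": t.ase_category,
                "has_idr": t.has_idr,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def generate_chx_experiment(
    n_genes: int = 100,
    n_repressed: int = 20,
    log2_fold: float = 3.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """MII-oocyte translation-inhibition experiment (DMSO vs cycloheximide).

    Returns (dmso, chx, repressed_truth): replicate log2-intensity frames —
    DMSO with two replicates, CHX pooling 24 h and 48 h treatments (two
    replicates each) — where the first ``n_repressed`` genes are newly
    synthesized proteins planted ``log2_fold`` lower under CHX.
    """
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    base = rng.uniform(8.0, 14.0, size=n_genes)
    effect = np.zeros(n_genes)
    effect[:n_repressed] = -log2_fold
    dmso = pd.DataFrame(
        {f"DMSO_rep{r}": base + rng.normal(0, noise_sd, n_genes) for r in (1, 2)},
        index=genes,
    )
    chx = pd.DataFrame(
        {
            f"CHX{h}_rep{r}": base + effect + rng.normal(0, noise_sd, n_genes)
            for h in (24, 48)
            for r in (1, 2)
        },
        index=genes,
    )
    return dmso, chx, set(genes[:n_repressed])
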