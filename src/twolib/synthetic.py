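"""Synthetic data generation for the two-library expression pipeline.

Emulates the study design the pipeline targets: two pooled sequencing
libraries (one infected, one control, no biological replicates at the
library level), per-gene read counts that are Poisson around
condition-specific means, a designated differentially expressed (DE)
subset with known fold changes, toy GO/pathway annotations with one
planted enriched term per term type, replicate 2-DE spot volumes with
multiplicative noise, and qRT-PCR CT values constructed so that the
2^-ddCT fold equals a chosen truth.

Every generator is deterministic under ``SimulationConfig.seed``: each
operation draws from its own seed stream so outputs do not depend on
call order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "GroundTruth",
    "ReferenceSet",
    "SpotSim",
    "generate_reference",
    "assign_truth",
    "generate_counts",
    "generate_reads",
    "generate_spot_table",
    "simulate_all",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# distinct seed streams so each generator op is order-independent
_STREAM_REFERENCE = 1
_STREAM_TRUTH = 2
_STREAM_COUNTS = 3
_STREAM_READS = 4
_STREAM_SPOTS = 5


class ConfigError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults describe the emulated design at desk scale: two libraries of
    10^6 clean reads each, 2,000 genes with lengths uniform on
    300-3,000 bp, 10% of genes DE at tenfold change (both directions),
    toy annotations of 20 GO and 20 pathway terms with 25 members each,
    and three replicate 2-DE gels.
    """

    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (300, 3000)
    library_sizes: tuple[int, int] = (1_000_000, 1_000_000)
    de_fraction: float = 0.10
    fold_changes: tuple[float, ...] = (10.0, 0.1)
    n_terms: int = 20
    genes_per_term: int = 25
    seed: int = 0
    emit_reads: bool = False
    read_length: int = 49
    base_error_rate: float = 0.0
    n_spot_replicates: int = 3

    # expression model
    rpkm_sigma: float = 1.0          # lognormal spread of true expression
    overdispersion: float = 0.0      # >0 switches Poisson to gamma-Poisson (NB)

    # read contamination fractions (each exercises one raw-read filter)
    n_reads: int = 2000
    adaptor: str = "AGATCGGAAGAGC"
    adaptor_fraction: float = 0.0
    highn_fraction: float = 0.0
    lowq_fraction: float = 0.0

    # proteomics / qPCR
    n_spots: int = 30
    spot_de_fraction: float = 0.3
    absent_spot_fraction: float = 0.2
    spot_fold: float = 4.0
    spot_cv: float = 0.10
    n_qpcr_genes: int = 12

    # enrichment planting
    de_term_fraction: float = 0.8    # fraction of the planted term's members made DE

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if lo > hi or lo < 1:
            raise ConfigError(f"invalid gene_length_range {self.gene_length_range}")
        if any(n <= 0 for n in self.library_sizes):
            raise ConfigError("library sizes must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if any(fc <= 0 or fc == 1 for fc in self.fold_changes):
            raise ConfigError("fold_changes must be positive and != 1")
        for name in ("adaptor_fraction", "highn_fraction", "lowq_fraction",
                     "base_error_rate", "spot_de_fraction", "absent_spot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_spot_replicates < 2:
            raise ConfigError("n_spot_replicates must be >= 2")
        if self.emit_reads and self.read_length > lo:
            raise ConfigError(
                f"read_length {self.read_length} exceeds shortest possible gene ({lo} bp)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("gene_length_range", "library_sizes", "fold_changes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    de_gene_ids: set[str]
    true_fold_change: dict[str, float]  # infected/control multiplier, 1 if not DE
    true_mean_rpkm: dict[str, float]
    de_terms: set[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_gene_ids": sorted(self.de_gene_ids),
            "true_fold_change": self.true_fold_change,
            "true_mean_rpkm": self.true_mean_rpkm,
            "de_terms": sorted(self.de_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class ReferenceSet:
    """Toy unigene reference: gene table, annotations and sequences."""

    genes: pd.DataFrame         # gene_id, length_bp, description
    annotations: pd.DataFrame   # gene_id, term_id, term_type in {GO, pathway}
    sequences: dict[str, str]   # gene_id -> DNA string

    @property
    def lengths(self) -> pd.Series:
        return self.genes.set_index("gene_id")["length_bp"]


def generate_reference(config: SimulationConfig) -> ReferenceSet:
    """Build the gene universe and its toy GO/pathway annotations.

    Gene lengths are uniform over ``gene_length_range``; sequences are
    i.i.d. random DNA (unique with overwhelming probability at toy
    scale, so unique mapping is well defined). Each of ``n_terms`` GO
    and ``n_terms`` pathway terms annotates ``genes_per_term`` distinct
    genes sampled without replacement.
    """
    rng = config._rng(_STREAM_REFERENCE)
    width = max(5, len(str(config.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": lengths.astype(int),
            "description": [f"synthetic unigene {g}" for g in gene_ids],
        }
    )
    sequences = {
        g: bytes(rng.choice(_BASES, size=int(n))).decode()
        for g, n in zip(gene_ids, lengths)
    }

    rows = []
    per_term = min(config.genes_per_term, config.n_genes)
    for term_type, prefix in (("GO", "GO:"), ("pathway", "ko")):
        for t in range(1, config.n_terms + 1):
            term_id = f"{prefix}{t:05d}"
            members = rng.choice(gene_ids, size=per_term, replace=False)
            rows.extend((g, term_id, term_type) for g in sorted(members))
    annotations = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_type"])
    return ReferenceSet(genes=genes, annotations=annotations, sequences=sequences)


def assign_truth(config: SimulationConfig, reference: ReferenceSet) -> GroundTruth:
    """Choose true expression levels and the DE subset.

    True expression is lognormal (sigma ``rpkm_sigma``) scaled so that
    sum(RPKM * length) = 1e9, i.e. expected library totals match the
    configured library sizes. One GO term and one pathway term are
    planted as enriched: ``de_term_fraction`` of their members are
    forced into the DE subset before the remainder is drawn at random.
    """
    rng = config._rng(_STREAM_TRUTH)
    gene_ids = reference.genes["gene_id"].tolist()
    lengths = reference.genes["length_bp"].to_numpy(dtype=float)

    raw = rng.lognormal(mean=0.0, sigma=config.rpkm_sigma, size=config.n_genes)
    scale = 1e9 / float(np.sum(raw * lengths))
    rpkm = raw * scale
    true_mean_rpkm = {g: float(v) for g, v in zip(gene_ids, rpkm)}

    n_de = int(round(config.de_fraction * config.n_genes))
    de_ids: list[str] = []
    de_terms: set[str] = set()
    if n_de > 0:
        ann = reference.annotations
        for term_type in ("GO", "pathway"):
            terms = ann.loc[ann["term_type"] == term_type, "term_id"]
            if terms.empty:
                continue
            planted = sorted(terms.unique())[0]
            de_terms.add(planted)
            members = ann.loc[ann["term_id"] == planted, "gene_id"].tolist()
            k = int(round(config.de_term_fraction * len(members)))
            picked = rng.choice(members, size=min(k, len(members)), replace=False)
            de_ids.extend(p for p in picked if p not in de_ids)
        de_ids = de_ids[:n_de]
        remaining = [g for g in gene_ids if g not in set(de_ids)]
        extra = n_de - len(de_ids)
        if extra > 0:
            de_ids.extend(rng.choice(remaining, size=extra, replace=False))

    fold = {g: 1.0 for g in gene_ids}
    if de_ids:
        fcs = rng.choice(np.asarray(config.fold_changes, dtype=float), size=len(de_ids))
        for g, fc in zip(de_ids, fcs):
            fold[g] = float(fc)

    return GroundTruth(
        de_gene_ids=set(de_ids),
        true_fold_change=fold,
        true_mean_rpkm=true_mean_rpkm,
        de_terms=de_terms,
    )


def generate_counts(config: SimulationConfig, truth: GroundTruth,
                    reference: ReferenceSet):
    """Draw per-gene counts for the control and infected libraries.

    The expected count of gene g in library j is
    ``RPKM_true(g) * FC_j(g) * N_j * L_g / 1e9`` with FC_j = 1 in the
    control library. Counts are Poisson; with ``overdispersion`` a > 0
    they are gamma-Poisson with mean unchanged and variance
    mu + a * mu^2.
    """
    from .readqc import LibraryCounts  # local import avoids a cycle at import time

    rng = config._rng(_STREAM_COUNTS)
    gene_ids = reference.genes["gene_id"].tolist()
    lengths = reference.genes["length_bp"].to_numpy(dtype=float)
    rpkm = np.array([truth.true_mean_rpkm[g] for g in gene_ids])
    fc = np.array([truth.true_fold_change[g] for g in gene_ids])
    n1, n2 = config.library_sizes

    out = []
    for sample_id, n_lib, mult in (("control", n1, np.ones_like(fc)), ("infected", n2, fc)):
        mu = rpkm * mult * n_lib * lengths / 1e9
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            mu = rng.gamma(shape, mu / shape)
        counts = rng.poisson(mu)
        out.append(
            LibraryCounts(
                sample_id=sample_id,
                counts=pd.Series(counts, index=gene_ids, name="count"),
                library_size=int(n_lib),
            )
        )
    return tuple(out)


def _phred_string(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def generate_reads(config: SimulationConfig, reference: ReferenceSet):
    """Sample toy FASTQ reads with known origin and planted contamination.

    Reads are drawn from gene bodies (gene chosen uniformly, start
    position uniform) with per-base substitution at ``base_error_rate``.
    Disjoint fractions of reads are contaminated to exercise each
    raw-read filter: adaptor carriers (the adaptor literal overwrites
    the read centre), high-N reads (20% of bases set to N) and
    low-quality reads (60% of bases at Phred 2).

    Returns ``(records, origins, contamination)`` where records is a list
    of ``readqc.ReadRecord``, origins maps read id -> source gene id and
    contamination maps read id -> {"clean","adaptor","highn","lowq"}.
    """
    from .readqc import ReadRecord

    if not config.emit_reads:
        raise ConfigError("generate_reads requires emit_reads=True")
    rng = config._rng(_STREAM_READS)
    gene_ids = reference.genes["gene_id"].tolist()
    k = config.read_length
    too_short = [g for g in gene_ids if len(reference.sequences[g]) < k]
    if too_short:
        raise ConfigError(f"read_length {k} exceeds length of genes {too_short[:3]}")

    p_clean = 1.0 - config.adaptor_fraction - config.highn_fraction - config.lowq_fraction
    if p_clean < 0:
        raise ConfigError("contamination fractions sum to more than 1")
    categories = rng.choice(
        np.array(["adaptor", "highn", "lowq", "clean"]),
        size=config.n_reads,
        p=[config.adaptor_fraction, config.highn_fraction, config.lowq_fraction, p_clean],
    )

    records, origins, contamination = [], {}, {}
    for i, cat in enumerate(categories):
        rid = f"r{i:06d}"
        gene = gene_ids[int(rng.integers(len(gene_ids)))]
        seq_full = reference.sequences[gene]
        start = int(rng.integers(len(seq_full) - k + 1))
        base = np.frombuffer(seq_full[start:start + k].encode(), dtype="S1").copy()
        if config.base_error_rate > 0:
            hits = np.nonzero(rng.random(k) < config.base_error_rate)[0]
            for pos in hits:
                choices = _BASES[_BASES != base[pos]]
                base[pos] = choices[int(rng.integers(len(choices)))]
        quals = rng.integers(30, 41, size=k)
        if cat == "adaptor":
            mid = (k - len(config.adaptor)) // 2
            base[mid:mid + len(config.adaptor)] = np.frombuffer(
                config.adaptor.encode(), dtype="S1")
        elif cat == "highn":
            n_n = max(int(math.floor(0.20 * k)), int(math.floor(0.10 * k)) + 1)
            pos = rng.choice(k, size=n_n, replace=False)
            base[pos] = b"N"
        elif cat == "lowq":
            n_low = max(int(math.floor(0.60 * k)), int(math.floor(0.50 * k)) + 1)
            pos = rng.choice(k, size=n_low, replace=False)
            quals[pos] = 2
        records.append(ReadRecord(rid, bytes(base.tobytes()).decode(), quals.astype(int)))
        origins[rid] = gene
        contamination[rid] = str(cat)
    return records, origins, contamination


def write_fastq(records, path: str | Path) -> None:
    """Write ReadRecords as Sanger (Phred+33) FASTQ."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{_phred_string(r.qualities)}\n")


@dataclass
class SpotSim:
    """Synthetic 2-DE spot volumes, qPCR CT table and accession mapping."""

    spots: pd.DataFrame        # spot_id, accession, condition, replicate, vol_percent, protein_name
    qpcr: pd.DataFrame         # gene_id + four CT columns
    mapping: pd.DataFrame      # accession, gene_id
    spot_truth: dict[str, str]     # spot_id -> planted category
    qpcr_truth: dict[str, float]   # gene_id -> planted 2^-ddCT fold


def generate_spot_table(config: SimulationConfig, truth: GroundTruth,
                        reference: ReferenceSet) -> SpotSim:
    """Build replicate spot volumes and CT values consistent with truth.

    Spot categories (planted): ``up``/``down`` spots with true volume
    ratio ``spot_fold`` (resp. its inverse), ``infected_only``/
    ``control_only`` presence/absence spots, and unchanged spots at
    ratio 1. Replicate volumes are lognormal around the condition mean
    with coefficient of variation ``spot_cv``. Each spot's accession is
    mapped to a gene whose true transcript direction agrees with the
    spot where one exists, so generator concordance is known.

    CT values are constructed to invert the 2^-ddCT model exactly:
    reference CT 20 in both conditions, target CT 25 in control and
    25 - log2(fold) in infected.
    """
    rng = config._rng(_STREAM_SPOTS)
    n = config.n_spots
    n_absent = int(round(config.absent_spot_fraction * n))
    n_de = int(round(config.spot_de_fraction * n))
    cats = (["infected_only"] * (n_absent - n_absent // 2)
            + ["control_only"] * (n_absent // 2)
            + ["up"] * (n_de - n_de // 2)
            + ["down"] * (n_de // 2))
    cats += ["unchanged"] * (n - len(cats))
    cats = cats[:n]

    up_genes = sorted(g for g in truth.de_gene_ids if truth.true_fold_change[g] > 1)
    down_genes = sorted(g for g in truth.de_gene_ids if truth.true_fold_change[g] < 1)
    flat_genes = sorted(set(reference.genes["gene_id"]) - truth.de_gene_ids)
    pools = {
        "up": up_genes or flat_genes,
        "infected_only": up_genes or flat_genes,
        "down": down_genes or flat_genes,
        "control_only": down_genes or flat_genes,
        "unchanged": flat_genes or sorted(reference.genes["gene_id"]),
    }

    sigma = math.sqrt(math.log(1.0 + config.spot_cv**2))
    rows, mapping_rows, spot_truth = [], [], {}
    for i, cat in enumerate(cats):
        spot_id = f"S{i + 1:03d}"
        accession = f"gi|{900000 + i}"
        pool = pools[cat]
        gene = pool[int(rng.integers(len(pool)))]
        mapping_rows.append((accession, gene))
        spot_truth[spot_id] = cat
        base = float(rng.uniform(0.05, 1.0))  # control-side mean vol.%
        if cat == "up":
            means = (base, base * config.spot_fold)
        elif cat == "down":
            means = (base, base / config.spot_fold)
        elif cat == "infected_only":
            means = (0.0, base)
        elif cat == "control_only":
            means = (base, 0.0)
        else:
            means = (base, base)
        for cond, mu in zip(("control", "infected"), means):
            for rep in range(1, config.n_spot_replicates + 1):
                if mu == 0.0:
                    vol = 0.0
                else:
                    vol = float(mu * rng.lognormal(-0.5 * sigma**2, sigma))
                rows.append((spot_id, accession, cond, rep, vol, f"synthetic protein {spot_id}"))
    spots = pd.DataFrame(
        rows,
        columns=["spot_id", "accession", "condition", "replicate", "vol_percent", "protein_name"],
    )
    mapping = pd.DataFrame(mapping_rows, columns=["accession", "gene_id"])

    # qPCR panel mixes up, down and unchanged genes, as a validation set would
    qpcr_pool: list[str] = []
    sources = [list(up_genes), list(down_genes), list(flat_genes)]
    while len(qpcr_pool) < config.n_qpcr_genes and any(sources):
        for src in sources:
            if src and len(qpcr_pool) < config.n_qpcr_genes:
                qpcr_pool.append(src.pop(0))
    qrows, qpcr_truth = [], {}
    for g in qpcr_pool:
        fold = truth.true_fold_change.get(g, 1.0)
        qpcr_truth[g] = float(fold)
        ct_ref = 20.0
        ct_tc = 25.0
        ct_ti = 25.0 - math.log2(fold)
        qrows.append((g, ct_ti, ct_tc, ct_ref, ct_ref))
    qpcr = pd.DataFrame(
        qrows,
        columns=["gene_id", "ct_target_infected", "ct_target_control",
                 "ct_ref_infected", "ct_ref_control"],
    )
    return SpotSim(spots=spots, qpcr=qpcr, mapping=mapping,
                   spot_truth=spot_truth, qpcr_truth=qpcr_truth)


@dataclass
class SimulatedStudy:
    """Everything one seeded run of the generator produced."""

    config: SimulationConfig
    reference: ReferenceSet
    truth: GroundTruth
    control: "object"   # readqc.LibraryCounts
    infected: "object"
    spot_sim: SpotSim
    reads: list | None = None
    read_origins: dict | None = None
    read_contamination: dict | None = None


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage once under one seed."""
    reference = generate_reference(config)
    truth = assign_truth(config, reference)
    control, infected = generate_counts(config, truth, reference)
    spot_sim = generate_spot_table(config, truth, reference)
    reads = origins = contamination = None
    if config.emit_reads:
        reads, origins, contamination = generate_reads(config, reference)
    return SimulatedStudy(
        config=config, reference=reference, truth=truth,
        control=control, infected=infected, spot_sim=spot_sim,
        reads=reads, read_origins=origins, read_contamination=contamination,
    )
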