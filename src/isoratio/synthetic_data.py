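"""Seeded synthetic data with the structure the pipeline assumes.

The generator realizes the uniform-coverage two-isoform model forwards:
a full-length transcript at per-nucleotide coverage ``a`` and an
alternate-start variant at coverage ``b`` over the shared 3' exons, so
exon ``i`` expects ``a*len_i`` reads before the variant start and
``(a+b)*len_i`` reads after.  Counts are emitted either noiselessly
(rounded means) or with Poisson noise, matching the uniform-reads
assumption; negative-binomial overdispersion is available for
robustness checks.

The default cohort emulates a paired tumor/normal breast-cancer design:
87 pairs, variant expression strongly tumor-enriched, larger in ER+
tumors than ER−, and relapse-free survival whose hazard depends on
variant positivity.  Everything is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .gene_model import ExonInterval, GeneModel
from .quantify import ExonCounts


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth coverages for one synthetic sample."""

    sample_id: str
    a: float  # full-length per-nucleotide coverage (reads/bp)
    b: float  # variant per-nucleotide coverage (reads/bp)

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise SimulationError("coverages must be >= 0")

    @property
    def rho(self) -> float:
        """True variant:full-length ratio b/a (requires a > 0)."""
        if self.a == 0:
            raise SimulationError(f"rho undefined for {self.sample_id!r}: a = 0")
        return self.b / self.a


@dataclass
class SimConfig:
    """Parameters of the synthetic gene and cohort.

    Coverage and ratio parameters are on the natural-log scale of
    lognormal distributions.  Defaults encode a strongly tumor-enriched
    variant (normal-tissue ratio centred near e^-4 ~ 0.02, tumor ratio
    near 1 in ER+ and e^-1.5 ~ 0.2 in ER−) at ~50x full-length
    coverage, which gives the paired design its expected >0.9 fraction
    of pairs with a log2-ratio difference above 1.
    """

    # gene structure
    n_exons: int = 15
    variant_start_exon: int = 10
    exon_length: int | list[int] = 100
    chrom: str = "chr3"
    gene_start: int = 10_000
    intron_length: int = 500
    strand: str = "+"

    # count noise
    noise: str = "poisson"  # none | poisson | nb
    nb_dispersion: float = 10.0  # NB size parameter (smaller = more overdispersed)
    library_size: int = 10_000_000

    # cohort block
    n_pairs: int = 87
    log_a_mean: float = float(np.log(50.0))
    log_a_sigma: float = 0.3
    tumor_log_rho_mean_er_pos: float = 0.5
    tumor_log_rho_mean_er_neg: float = -1.5
    tumor_log_rho_sigma: float = 1.0
    normal_log_rho_mean: float = -4.0
    normal_log_rho_sigma: float = 1.0
    er_pos_prevalence: float = 0.7
    her2_pos_prevalence: float = 0.2
    pr_pos_given_er_pos: float = 0.8
    pr_pos_given_er_neg: float = 0.2
    grade_probs: tuple[float, float, float] = (0.15, 0.45, 0.40)
    tp53_mut_prevalence: float = 0.3

    # survival block (months)
    positivity_threshold: float = 0.1
    median_rfs_negative: float = 60.0
    hazard_ratio_positive: float = 0.5
    censoring_rate: float = 1.0 / 120.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_exons < 2 or not 1 < self.variant_start_exon <= self.n_exons:
            raise SimulationError("need n_exons >= 2 and 1 < variant_start_exon <= n_exons")
        if self.noise not in ("none", "poisson", "nb"):
            raise SimulationError(f"unknown noise model {self.noise!r}")
        for p in (self.er_pos_prevalence, self.her2_pos_prevalence,
                  self.pr_pos_given_er_pos, self.pr_pos_given_er_neg,
                  self.tp53_mut_prevalence):
            if not 0 <= p <= 1:
                raise SimulationError("prevalences must lie in [0, 1]")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9 or min(self.grade_probs) < 0:
            raise SimulationError("grade_probs must be a probability vector")
        if self.n_pairs < 1:
            raise SimulationError("n_pairs must be >= 1")
        if self.median_rfs_negative <= 0 or self.hazard_ratio_positive <= 0:
            raise SimulationError("survival parameters must be positive")
        if self.censoring_rate < 0:
            raise SimulationError("censoring_rate must be >= 0")


def build_gene_model(config: SimConfig) -> GeneModel:
    """Synthetic gene with the configured exon count and lengths."""
    config.validate()
    if isinstance(config.exon_length, int):
        lengths = [config.exon_length] * config.n_exons
    else:
        lengths = list(config.exon_length)
        if len(lengths) != config.n_exons:
            raise SimulationError("exon_length list must match n_exons")
    exons = []
    pos = config.gene_start
    for i, length in enumerate(lengths, start=1):
        exons.append(
            ExonInterval(chrom=config.chrom, start=pos, end=pos + length,
                         index=i, strand="+")
        )
        pos += length + config.intron_length
    if config.strand == "-":
        # mirror ordinals so exon 1 is genomically last
        n = len(exons)
        exons = [
            ExonInterval(chrom=e.chrom, start=e.start, end=e.end,
                         index=n - e.index + 1, strand="-")
            for e in exons
        ]
    return GeneModel(
        gene_id="SYNGENE", exons=tuple(exons),
        variant_start_exon=config.variant_start_exon,
    )


def expected_counts(truth: SimTruth, model: GeneModel) -> np.ndarray:
    """Expected exon counts under the uniform-coverage two-isoform model."""
    mu = np.empty(model.n_exons, dtype=float)
    for e in model.exons:
        cov = truth.a if e.index < model.variant_start_exon else truth.a + truth.b
        mu[e.index - 1] = cov * e.length
    return mu


def simulate_counts(
    truth: SimTruth,
    model: GeneModel,
    noise: str = "poisson",
    seed: int | np.random.Generator = 0,
    *,
    nb_dispersion: float = 10.0,
    library_size: int = 10_000_000,
) -> ExonCounts:
    """Draw one sample's exon counts from the forward model."""
    if truth.a == 0 and truth.b == 0:
        raise SimulationError("at least one of a, b must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = expected_counts(truth, model)
    if noise == "none":
        counts = np.round(mu).astype(np.int64)
    elif noise == "poisson":
        counts = rng.poisson(mu).astype(np.int64)
    elif noise == "nb":
        # Gamma-Poisson mixture with shape nb_dispersion
        lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
        counts = rng.poisson(lam).astype(np.int64)
    else:
        raise SimulationError(f"unknown noise model {noise!r}")
    return ExonCounts(sample_id=truth.sample_id, counts=counts,
                      total_mapped_reads=library_size)


@dataclass
class SimulatedCohort:
    model: GeneModel
    counts: dict[str, ExonCounts]
    sheet: pd.DataFrame
    truth: pd.DataFrame


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Paired tumor/normal cohort with clinical structure and survival.

    Per pair: ER/Her2/PR/grade/TP53 are drawn from the configured
    prevalences; both tissues share a lognormal full-length coverage;
    the tumor's variant ratio is drawn from an ER-dependent lognormal
    and the normal's from a low-centred lognormal.  Relapse-free
    survival is exponential with a positivity-dependent hazard and
    independent exponential censoring.  Positivity in the sheet is the
    ground-truth call (true tumor rho against the threshold), standing
    in for an assay-based call.
    """
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = build_gene_model(config)

    counts: dict[str, ExonCounts] = {}
    sheet_rows = []
    truth_rows = []
    lam_neg = np.log(2.0) / config.median_rfs_negative
    for i in range(1, config.n_pairs + 1):
        pair = f"P{i:03d}"
        er = "pos" if rng.random() < config.er_pos_prevalence else "neg"
        her2 = "pos" if rng.random() < config.her2_pos_prevalence else "neg"
        pr_p = (config.pr_pos_given_er_pos if er == "pos"
                else config.pr_pos_given_er_neg)
        pr = "pos" if rng.random() < pr_p else "neg"
        grade = str(1 + rng.choice(3, p=list(config.grade_probs)))
        tp53 = "Mut" if rng.random() < config.tp53_mut_prevalence else "WT"

        a = float(np.exp(rng.normal(config.log_a_mean, config.log_a_sigma)))
        mu_t = (config.tumor_log_rho_mean_er_pos if er == "pos"
                else config.tumor_log_rho_mean_er_neg)
        rho_t = float(np.exp(rng.normal(mu_t, config.tumor_log_rho_sigma)))
        rho_n = float(np.exp(rng.normal(config.normal_log_rho_mean,
                                        config.normal_log_rho_sigma)))

        positivity = ("positive" if rho_t >= config.positivity_threshold
                      else "negative")
        hazard = lam_neg * (config.hazard_ratio_positive
                            if positivity == "positive" else 1.0)
        event_time = float(rng.exponential(1.0 / hazard))
        if config.censoring_rate > 0:
            censor_time = float(rng.exponential(1.0 / config.censoring_rate))
        else:
            censor_time = float("inf")
        rfs_time = round(min(event_time, censor_time), 2)
        event = "relapse" if event_time <= censor_time else "censored"

        for tissue, rho in (("tumor", rho_t), ("normal", rho_n)):
            sid = f"{pair}_{'T' if tissue == 'tumor' else 'N'}"
            truth = SimTruth(sample_id=sid, a=a, b=a * rho)
            counts[sid] = simulate_counts(
                truth, model, noise=config.noise, seed=rng,
                nb_dispersion=config.nb_dispersion,
                library_size=config.library_size,
            )
            truth_rows.append({"sample_id": sid, "a": a, "b": a * rho, "rho": rho})
            sheet_rows.append({
                "sample_id": sid, "pair_id": pair, "tissue": tissue,
                "er": er, "her2": her2, "pr": pr, "grade": grade, "tp53": tp53,
                "rfs_time": rfs_time if tissue == "tumor" else "",
                "event": event if tissue == "tumor" else "unknown",
                "positivity": positivity if tissue == "tumor" else "unknown",
            })

    sheet = pd.DataFrame(sheet_rows)
    sheet["rfs_time"] = pd.to_numeric(sheet["rfs_time"], errors="coerce")
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(model=model, counts=counts, sheet=sheet, truth=truth)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Write the cohort in the same dialects the pipeline reads."""
    from .gene_model import write_gtf, write_model_json
    from .quantify import write_counts_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gtf(cohort.model, out / "gene.gtf")
    write_model_json(cohort.model, out / "gene_model.json")
    write_counts_tsv(cohort.counts, out / "exon_counts.tsv")
    sheet = cohort.sheet.copy()
    sheet["rfs_time"] = sheet["rfs_time"].map(
        lambda x: "" if pd.isna(x) else f"{x:g}"
    )
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def write_reads_sam(
    counts: ExonCounts,
    model: GeneModel,
    path: str | Path,
    *,
    read_length: int = 29,
    seed: int = 0,
) -> None:
    """Emit the exon counts as single-end reads in a SAM file.

    Each exon's count becomes that many fully-contained reads at
    uniform-random starts, so re-counting the file reproduces the input
    counts exactly.  Exists to exercise the alignment-counting path.
    """
    rng = np.random.default_rng(seed)
    max_end = max(e.end for e in model.exons)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.chrom, "LN": max_end + 1000}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        serial = 0
        for e in model.exons:
            n_reads = int(counts.counts[e.index - 1])
            if e.length < read_length and n_reads > 0:
                raise SimulationError(
                    f"exon {e.index} ({e.length} bp) shorter than read length"
                )
            starts = rng.integers(e.start, e.end - read_length + 1, size=n_reads)
            for s in np.sort(starts):
                serial += 1
                seg = pysam.AlignedSegment()
                seg.query_name = f"read{serial:07d}"
                seg.query_sequence = "A" * read_length
                seg.flag = 0
                seg.reference_id = 0
                seg.reference_start = int(s)
                seg.mapping_quality = 60
                seg.cigarstring = f"{read_length}M"
                seg.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                out.write(seg)
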