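"""Exon-level read counting and closed-form two-isoform deconvolution.

The model: one gene with exons 1..n emits two transcripts — the
full-length transcript over all exons and an alternate-start variant
over the shared 3' exons k..n — and reads per unit nucleotide are
uniform within each transcript.  Writing ``a`` and ``b`` for the two
per-nucleotide coverages, the expected raw read count of exon ``i`` of
length ``len_i`` is ``a*len_i`` for ``i < k`` and ``(a+b)*len_i`` for
``i >= k``.  Summing raw counts into ``r0`` (exons 1..k-1, exclusive to
the full-length transcript) and ``r1`` (exons k..n, shared) gives a
closed-form deconvolution:

    F0 = r0 * L0 / (L0 - L1)        reads assignable to full-length
    F1 = r1 - F0 * L1 / L0          reads assignable to the variant
    R  = (F1 / L1) / (F0 / L0)      variant : full-length mRNA ratio

``R`` equals ``b/a`` exactly on noiseless data.  Counts must be raw
integers — not RPKM, not log-transformed — because the cancellation
above operates on read counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .gene_model import GeneModel, exon_lengths

# quality flags on a RatioEstimate
F1_CLIPPED_NEGATIVE = "F1_CLIPPED_NEGATIVE"
R_UNDEFINED_ZERO_F0 = "R_UNDEFINED_ZERO_F0"
LOW_COUNTS = "LOW_COUNTS"

#: total gene reads below which LOW_COUNTS is flagged
DEFAULT_MIN_TOTAL_READS = 10
#: pseudocount added to R before log2 (the variant may be truly absent)
DEFAULT_EPSILON = 1e-6


class QuantifyError(ValueError):
    pass


@dataclass
class ExonCounts:
    """Raw integer read counts per exon ordinal for one sample."""

    sample_id: str
    counts: np.ndarray
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise QuantifyError(
                    f"sample {self.sample_id!r}: exon counts must be raw integers"
                )
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise QuantifyError(f"sample {self.sample_id!r}: negative exon count")
        if self.total_mapped_reads < 0:
            raise QuantifyError(f"sample {self.sample_id!r}: negative library size")
        self.counts = arr.astype(np.int64)


@dataclass
class RatioEstimate:
    """Deconvolution result for one sample.

    ``R`` is non-negative after clipping (``math.inf`` sentinel when
    r0 = 0 but variant reads are present); ``f1_raw`` preserves the
    unclipped value for diagnostics.
    """

    sample_id: str
    r0: int
    r1: int
    f0: float
    f1_raw: float
    f1: float
    R: float
    log2R: float
    flags: frozenset[str] = frozenset()


@dataclass
class ExonExpression:
    """Per-exon RPKM profile (reads per kb of exon per million mapped reads)."""

    sample_id: str
    rpkm: np.ndarray
    log2_rpkm: np.ndarray


def split_counts(counts: ExonCounts, model: GeneModel) -> tuple[int, int]:
    """Sum counts into (r0, r1): exclusive 5' exons vs shared 3' exons."""
    if len(counts.counts) != model.n_exons:
        raise QuantifyError(
            f"sample {counts.sample_id!r}: {len(counts.counts)} exon counts for a "
            f"{model.n_exons}-exon model"
        )
    k = model.variant_start_exon
    r0 = int(counts.counts[: k - 1].sum())
    r1 = int(counts.counts[k - 1 :].sum())
    return r0, r1


def estimate_isoform_ratio(
    counts: ExonCounts,
    model: GeneModel,
    *,
    epsilon: float = DEFAULT_EPSILON,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
) -> RatioEstimate:
    """Closed-form deconvolution of variant vs full-length abundance.

    Boundary policy: a negative raw F1 (sampling noise on a sample with
    little or no variant) is clipped to 0 for R and flagged; r0 = 0 with
    r1 > 0 means no full-length signal, so R is the ``inf`` sentinel and
    flagged rather than a division error; an (almost) empty gene is
    flagged LOW_COUNTS.
    """
    L0, L1 = model.L0, model.L1
    if not L0 > L1 > 0:
        raise QuantifyError(f"need L0 > L1 > 0, got L0={L0}, L1={L1}")
    r0, r1 = split_counts(counts, model)

    flags: set[str] = set()
    if r0 + r1 < min_total_reads:
        flags.add(LOW_COUNTS)

    if r0 + r1 == 0:
        return RatioEstimate(
            sample_id=counts.sample_id, r0=0, r1=0, f0=0.0, f1_raw=0.0, f1=0.0,
            R=0.0, log2R=math.log2(epsilon), flags=frozenset(flags),
        )
    if r0 == 0:
        # all signal in the shared exons: pure variant, full-length undetected
        flags.add(R_UNDEFINED_ZERO_F0)
        return RatioEstimate(
            sample_id=counts.sample_id, r0=0, r1=r1, f0=0.0, f1_raw=float(r1),
            f1=float(r1), R=math.inf, log2R=math.inf, flags=frozenset(flags),
        )

    f0 = r0 * L0 / (L0 - L1)
    f1_raw = r1 - f0 * L1 / L0
    if f1_raw < 0:
        flags.add(F1_CLIPPED_NEGATIVE)
        f1 = 0.0
    else:
        f1 = f1_raw
    R = (f1 / L1) / (f0 / L0)
    return RatioEstimate(
        sample_id=counts.sample_id, r0=r0, r1=r1, f0=f0, f1_raw=f1_raw, f1=f1,
        R=R, log2R=math.log2(R + epsilon), flags=frozenset(flags),
    )


def compute_exon_rpkm(counts: ExonCounts, model: GeneModel) -> ExonExpression:
    """Per-exon RPKM and log2(RPKM + 1) profile for plotting exon usage."""
    if counts.total_mapped_reads <= 0:
        raise QuantifyError(
            f"sample {counts.sample_id!r}: total_mapped_reads must be > 0 for RPKM"
        )
    lengths = np.asarray(exon_lengths(model), dtype=float)
    if len(counts.counts) != model.n_exons:
        raise QuantifyError(
            f"sample {counts.sample_id!r}: counts length mismatch with model"
        )
    rpkm = counts.counts * 1e9 / (lengths * counts.total_mapped_reads)
    return ExonExpression(
        sample_id=counts.sample_id, rpkm=rpkm, log2_rpkm=np.log2(rpkm + 1.0)
    )


def call_positivity(estimate: RatioEstimate, threshold: float = 0.1) -> str:
    """Binary presence call for the variant: ``R >= threshold`` is positive.

    This is a sequencing surrogate for an endpoint PCR band call.  The
    pure-variant sentinel (no full-length signal, variant reads present)
    is positive by policy.
    """
    if threshold < 0:
        raise QuantifyError(f"positivity threshold must be >= 0, got {threshold}")
    if R_UNDEFINED_ZERO_F0 in estimate.flags:
        return "positive"
    return "positive" if estimate.R >= threshold else "negative"


# ---------------------------------------------------------------------------
# read counting


def count_exon_reads(
    alignment_path: str | Path, model: GeneModel, sample_id: str | None = None
) -> ExonCounts:
    """Count primary mapped reads per exon from a SAM/BAM file.

    Each primary, mapped read is assigned to the exon with which its
    aligned blocks share the most bases (ties go to the lower ordinal);
    reads overlapping no exon are ignored.  ``total_mapped_reads`` is
    the number of primary mapped reads in the whole file, the library
    size RPKM needs.
    """
    path = Path(alignment_path)
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    counts = np.zeros(model.n_exons, dtype=np.int64)
    total = 0
    exon_spans = [(e.start, e.end, e.index) for e in model.exons]
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        references = set(af.references or ())
        if references and model.chrom not in references:
            raise QuantifyError(
                f"chromosome {model.chrom!r} of gene {model.gene_id!r} not among "
                f"alignment references {sorted(references)}"
            )
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.reference_name != model.chrom:
                continue
            best_idx, best_overlap = None, 0
            for start, end, index in exon_spans:
                overlap = sum(
                    max(0, min(end, b_end) - max(start, b_start))
                    for b_start, b_end in read.get_blocks()
                )
                # strict > keeps ties at the lower ordinal (spans are in
                # transcription order and scanned once)
                if overlap > best_overlap:
                    best_idx, best_overlap = index, overlap
            if best_idx is not None:
                counts[best_idx - 1] += 1
    return ExonCounts(
        sample_id=sample_id or path.stem, counts=counts, total_mapped_reads=total
    )


# ---------------------------------------------------------------------------
# tabular interfaces


def read_counts_tsv(path: str | Path) -> dict[str, ExonCounts]:
    """Read a long-format exon count table.

    Required columns: ``sample_id``, ``exon_index``, ``count`` (header
    required).  An optional ``total_mapped_reads`` column supplies the
    library size; otherwise the per-sample count sum is used.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise QuantifyError(f"cannot parse count table {path}: {exc}") from exc
    required = {"sample_id", "exon_index", "count"}
    missing = required - set(df.columns)
    if missing:
        raise QuantifyError(
            f"count table {path} lacks required column(s): {', '.join(sorted(missing))}"
        )
    for col in ("exon_index", "count"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            line = int(bad.index[0]) + 2  # +1 header, +1 one-based
            raise QuantifyError(
                f"count table {path}: non-numeric {col!r} at line {line}"
            )
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    out: dict[str, ExonCounts] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("exon_index")
        idx = grp["exon_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise QuantifyError(
                f"count table {path}: sample {sample_id!r} exon indices are not 1..n"
            )
        if "total_mapped_reads" in grp.columns:
            total = int(grp["total_mapped_reads"].iloc[0])
        else:
            total = int(grp["count"].sum())
        out[str(sample_id)] = ExonCounts(
            sample_id=str(sample_id), counts=grp["count"].to_numpy(), total_mapped_reads=total
        )
    return out


def write_counts_tsv(
    counts: dict[str, ExonCounts] | list[ExonCounts], path: str | Path
) -> None:
    items = counts.values() if isinstance(counts, dict) else counts
    rows = [
        {
            "sample_id": c.sample_id,
            "exon_index": i + 1,
            "count": int(v),
            "total_mapped_reads": c.total_mapped_reads,
        }
        for c in items
        for i, v in enumerate(c.counts)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def estimates_to_frame(estimates: list[RatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "r0": e.r0,
                "r1": e.r1,
                "F0": e.f0,
                "F1_raw": e.f1_raw,
                "F1": e.f1,
                "R": e.R,
                "log2R": e.log2R,
                "flags": ";".join(sorted(e.flags)),
            }
            for e in estimates
        ]
    )


def write_estimates_tsv(estimates: list[RatioEstimate], path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(path, sep="\t", index=False)


def read_estimates_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "R", "log2R"}
    missing = required - set(df.columns)
    if missing:
        raise QuantifyError(
            f"estimate table {path} lacks required column(s): {', '.join(sorted(missing))}"
        )
    df["flags"] = df.get("flags", pd.Series([""] * len(df))).fillna("")
    return df
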