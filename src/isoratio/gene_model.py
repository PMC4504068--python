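"""Exon structure of a single gene and the length constants of the
two-isoform deconvolution.

The estimator in :mod:`isoratio.quantify` compares an alternate-start
(variant) transcript that shares the 3' exons of a gene with the
full-length transcript.  All it needs from the annotation is the ordered
exon intervals, the ordinal ``k`` of the first exon shared by the
variant, and two length constants:

* ``L0`` — summed exon length of the full transcript (exons 1..n),
* ``L1`` — summed exon length of the shared 3' exons (exons k..n).

Internal coordinates are 0-based, half-open.  GTF input (1-based,
inclusive) is converted on read; BED input is used as-is.  Exon ordinals
follow transcription order, so on the minus strand exon 1 is the
genomically last exon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gffutils


class GeneModelError(ValueError):
    """Invalid or inconsistent gene annotation."""


class GeneNotFoundError(GeneModelError):
    """The requested gene id is absent from the annotation file."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 0-based half-open, with its 1-based transcription-order ordinal."""

    chrom: str
    start: int
    end: int
    index: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GeneModelError(
                f"exon {self.index}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"exon {self.index}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Ordered exons of one gene plus the variant's first shared exon.

    Parameters
    ----------
    gene_id
        Identifier of the gene (e.g. an Ensembl id or symbol).
    exons
        Exons in transcription order, ordinals 1..n.
    variant_start_exon
        Ordinal ``k`` of the first exon the variant transcript shares
        with the full-length transcript (``1 < k <= n``).
    intronic_extension_bp
        Optional length of the variant's intronic 5' extension upstream
        of exon ``k``.  Recorded for documentation only; it never enters
        ``L1``, which is defined over shared exons.
    """

    gene_id: str
    exons: tuple[ExonInterval, ...]
    variant_start_exon: int
    intronic_extension_bp: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        n = len(self.exons)
        if n < 2:
            raise GeneModelError(f"gene {self.gene_id!r}: need at least 2 exons, got {n}")
        if sorted(e.index for e in self.exons) != list(range(1, n + 1)):
            raise GeneModelError(
                f"gene {self.gene_id!r}: exon indices must be consecutive 1..{n} "
                "with no duplicates"
            )
        if not 1 < self.variant_start_exon <= n:
            raise GeneModelError(
                f"gene {self.gene_id!r}: variant_start_exon={self.variant_start_exon} "
                f"out of range (2..{n})"
            )
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise GeneModelError(
                f"gene {self.gene_id!r}: exons span multiple chromosomes {sorted(chroms)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise GeneModelError(f"gene {self.gene_id!r}: exons mix strands")
        by_pos = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if b.start < a.end:
                raise GeneModelError(
                    f"gene {self.gene_id!r}: exons {a.index} and {b.index} overlap"
                )
        # ordinals must follow transcription order
        in_order = sorted(self.exons, key=lambda e: e.index)
        starts = [e.start for e in in_order]
        ascending = all(x < y for x, y in zip(starts, starts[1:]))
        descending = all(x > y for x, y in zip(starts, starts[1:]))
        expected = ascending if self.strand == "+" else descending
        if not expected:
            raise GeneModelError(
                f"gene {self.gene_id!r}: exon ordinals do not follow transcription "
                f"order on strand {self.strand!r}"
            )
        object.__setattr__(self, "exons", tuple(in_order))

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def L0(self) -> int:
        """Total exon length of the full-length transcript (bp)."""
        return sum(e.length for e in self.exons)

    @property
    def L1(self) -> int:
        """Total exon length of the shared 3' exons k..n (bp)."""
        return sum(e.length for e in self.exons if e.index >= self.variant_start_exon)


def exon_lengths(model: GeneModel) -> list[int]:
    """Per-exon lengths (bp) in transcription order; sums to ``model.L0``."""
    return [e.length for e in model.exons]


def _order_and_index(
    raw: list[tuple[str, int, int, str, int | None]], gene_id: str
) -> list[ExonInterval]:
    """Assign transcription-order ordinals, trusting explicit indices when given."""
    strand = raw[0][3]
    if all(r[4] is not None for r in raw):
        return [
            ExonInterval(chrom=c, start=s, end=e, index=i, strand=st)
            for c, s, e, st, i in raw
        ]
    ordered = sorted(raw, key=lambda r: r[1], reverse=(strand == "-"))
    return [
        ExonInterval(chrom=c, start=s, end=e, index=i + 1, strand=st)
        for i, (c, s, e, st, _) in enumerate(ordered)
    ]


def _load_gtf(path: Path, gene_id: str) -> list[ExonInterval]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    raw: list[tuple[str, int, int, str, int | None]] = []
    for feat in db.all_features(featuretype="exon"):
        if gene_id not in feat.attributes.get("gene_id", []):
            continue
        number = feat.attributes.get("exon_number")
        idx = int(number[0]) if number else None
        # GTF is 1-based inclusive; gffutils keeps that convention
        raw.append((feat.seqid, feat.start - 1, feat.end, feat.strand, idx))
    if not raw:
        raise GeneNotFoundError(f"gene not found: {gene_id!r} in {path}")
    return _order_and_index(raw, gene_id)


def _load_bed(path: Path, gene_id: str) -> list[ExonInterval]:
    """BED12 (one record, exons as blocks) or BED6+index (one exon per line)."""
    raw: list[tuple[str, int, int, str, int | None]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 12:  # BED12: blocks are the exons
                if f[3] != gene_id:
                    continue
                chrom, start, strand = f[0], int(f[1]), f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                for size, off in zip(sizes, offsets):
                    raw.append((chrom, start + off, start + off + size, strand, None))
            elif len(f) >= 7:  # BED6 + exon ordinal in column 7
                if f[3] != gene_id:
                    continue
                raw.append((f[0], int(f[1]), int(f[2]), f[5], int(f[6])))
            elif len(f) >= 6:
                if f[3] != gene_id:
                    continue
                raw.append((f[0], int(f[1]), int(f[2]), f[5], None))
            else:
                raise GeneModelError(f"unparseable BED line in {path}: {line!r}")
    if not raw:
        raise GeneNotFoundError(f"gene not found: {gene_id!r} in {path}")
    return _order_and_index(raw, gene_id)


def load_gene_model(
    annotation_path: str | Path,
    gene_id: str,
    variant_start_exon: int,
    *,
    fmt: str | None = None,
    intronic_extension_bp: int = 0,
) -> GeneModel:
    """Read one gene's exon structure from a GTF/GFF or BED annotation.

    ``fmt`` may be ``"gtf"``, ``"bed"`` or ``"json"``; by default it is
    inferred from the file extension.  GTF coordinates (1-based,
    inclusive) are shifted to the internal 0-based half-open convention;
    BED is already half-open.
    """
    path = Path(annotation_path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"gtf": "gtf", "gff": "gtf", "gff3": "gtf", "bed": "bed", "json": "json"}.get(
            suffix.lstrip("."), ""
        )
        if not fmt:
            raise GeneModelError(f"cannot infer annotation format from {path.name!r}")
    if fmt == "json":
        model = read_model_json(path)
        if model.gene_id != gene_id:
            raise GeneNotFoundError(f"gene not found: {gene_id!r} in {path}")
        return model
    exons = _load_gtf(path, gene_id) if fmt == "gtf" else _load_bed(path, gene_id)
    return GeneModel(
        gene_id=gene_id,
        exons=tuple(exons),
        variant_start_exon=variant_start_exon,
        intronic_extension_bp=intronic_extension_bp,
    )


# ---------------------------------------------------------------------------
# serialization


def write_model_json(model: GeneModel, path: str | Path) -> None:
    payload = {
        "gene_id": model.gene_id,
        "variant_start_exon": model.variant_start_exon,
        "intronic_extension_bp": model.intronic_extension_bp,
        "exons": [
            {"chrom": e.chrom, "start": e.start, "end": e.end, "index": e.index,
             "strand": e.strand}
            for e in model.exons
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model_json(path: str | Path) -> GeneModel:
    payload = json.loads(Path(path).read_text())
    exons = tuple(ExonInterval(**e) for e in payload["exons"])
    return GeneModel(
        gene_id=payload["gene_id"],
        exons=exons,
        variant_start_exon=payload["variant_start_exon"],
        intronic_extension_bp=payload.get("intronic_extension_bp", 0),
    )


def write_gtf(model: GeneModel, path: str | Path, *, source: str = "isoratio") -> None:
    """Write the model as a minimal ensembl-dialect GTF (1-based inclusive)."""
    lines = []
    for e in model.exons:
        attrs = (
            f'gene_id "{model.gene_id}"; transcript_id "{model.gene_id}.t1"; '
            f'exon_number "{e.index}";'
        )
        lines.append(
            "\t".join(
                [e.chrom, source, "exon", str(e.start + 1), str(e.end), ".",
                 e.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(model: GeneModel, path: str | Path) -> None:
    """Write the model as BED6+index (0-based half-open, ordinal in column 7)."""
    lines = []
    for e in model.exons:
        lines.append(
            "\t".join(
                [e.chrom, str(e.start), str(e.end), model.gene_id, "0", e.strand,
                 str(e.index)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
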