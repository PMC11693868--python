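"""Transcript models, abundance tables, and the on-disk dialects used everywhere else.

All coordinates are 0-based half-open internally.  GTF input/output converts
from/to the 1-based inclusive convention of that format.  The quantification
dialect is a single merged TSV (one row per transcript, one count and one FPKM
column per library) rather than per-library assembler output, which decouples
the pipeline from any particular quantifier's file layout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

Interval = tuple[int, int]

FRACTIONS = ("cytosolic", "ribosome")


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed; message names the line number."""


class ValidationError(ValueError):
    """Raised when parsed or supplied data violate a model invariant."""


# ---------------------------------------------------------------------------
# interval arithmetic (0-based half-open)
# ---------------------------------------------------------------------------

def normalize_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort intervals and merge overlapping or touching ones into canonical form."""
    ivs = sorted((int(a), int(b)) for a, b in intervals if int(b) > int(a))
    merged: list[list[int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


def subtract_intervals(minuend: Iterable[Interval], subtrahend: Iterable[Interval]) -> tuple[Interval, ...]:
    """Set difference minuend − subtrahend on normalized interval sets."""
    result: list[Interval] = []
    subs = normalize_intervals(subtrahend)
    for a, b in normalize_intervals(minuend):
        start = a
        for sa, sb in subs:
            if sb <= start or sa >= b:
                continue
            if sa > start:
                result.append((start, sa))
            start = max(start, sb)
            if start >= b:
                break
        if start < b:
            result.append((start, b))
    return tuple(result)


def intervals_length(intervals: Iterable[Interval]) -> int:
    return sum(b - a for a, b in intervals)


def intervals_contain(outer: Iterable[Interval], inner: Iterable[Interval]) -> bool:
    """True iff inner ⊆ outer as genomic point sets."""
    return not subtract_intervals(inner, outer)


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: exon/CDS structure plus derived UTR intervals.

    ``utr5``/``utr3`` are the untranslated exonic intervals upstream/downstream
    of the CDS in transcript orientation (so on the minus strand the 5'UTR sits
    at the genomically rightmost end).  Non-coding transcripts have empty
    ``cds``, ``utr5`` and ``utr3``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]
    length: int

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


def build_transcript(
    transcript_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Iterable[Interval],
    cds: Iterable[Interval] = (),
) -> TranscriptModel:
    """Assemble a :class:`TranscriptModel`, deriving UTRs as exon − CDS split by strand."""
    if strand not in {"+", "-"}:
        raise ValidationError(f"transcript {transcript_id}: strand must be '+' or '-', got {strand!r}")
    exons_n = normalize_intervals(exons)
    if not exons_n:
        raise ValidationError(f"transcript {transcript_id} has no exons")
    cds_n = normalize_intervals(cds)
    if cds_n and not intervals_contain(exons_n, cds_n):
        raise ValidationError(f"transcript {transcript_id}: CDS is not contained in exons")
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()
    if cds_n:
        cds_start, cds_end = cds_n[0][0], cds_n[-1][1]
        left: list[Interval] = []
        right: list[Interval] = []
        for a, b in subtract_intervals(exons_n, cds_n):
            if b <= cds_start:
                left.append((a, b))
            elif a >= cds_end:
                right.append((a, b))
            else:
                raise ValidationError(
                    f"transcript {transcript_id}: non-coding exon segment ({a},{b}) "
                    "interrupts the CDS span"
                )
        if strand == "+":
            utr5, utr3 = tuple(left), tuple(right)
        else:
            utr5, utr3 = tuple(right), tuple(left)
    length = intervals_length(exons_n)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons_n,
        cds=cds_n,
        utr5=utr5,
        utr3=utr3,
        length=length,
    )


@dataclass
class TranscriptCatalog:
    """Gene → transcript hierarchy with full transcript models."""

    genes: dict[str, list[str]] = field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, models: Iterable[TranscriptModel]) -> "TranscriptCatalog":
        genes: dict[str, list[str]] = {}
        transcripts: dict[str, TranscriptModel] = {}
        for m in models:
            if m.transcript_id in transcripts:
                raise ValidationError(f"duplicate transcript_id {m.transcript_id}")
            transcripts[m.transcript_id] = m
            genes.setdefault(m.gene_id, []).append(m.transcript_id)
        for txs in genes.values():
            txs.sort()
        return cls(genes=genes, transcripts=transcripts)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes[gene_id]]

    def tx2gene(self) -> pd.Series:
        """transcript_id → gene_id mapping as a pandas Series (sorted index)."""
        s = pd.Series({t: m.gene_id for t, m in self.transcripts.items()}, dtype=object)
        return s.sort_index()


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(path: str | Path, attributes_dialect: str = "ensembl-like") -> TranscriptCatalog:
    """Parse a GTF file (1-based inclusive) into a :class:`TranscriptCatalog`.

    Only ``exon`` and ``CDS`` features are consumed; every such feature must
    carry ``gene_id`` and ``transcript_id`` attributes.  UTRs are derived from
    the exon − CDS set difference, oriented by strand.
    """
    if attributes_dialect != "ensembl-like":
        raise ValueError(f"unsupported attributes dialect: {attributes_dialect}")
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path.name} line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in {"exon", "CDS"}:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"{path.name} line {lineno}: non-integer coordinates {start_s!r}, {end_s!r}") from None
            if start < 1 or end < start:
                raise GtfParseError(f"{path.name} line {lineno}: invalid coordinate range {start}-{end}")
            attr_map = dict(_ATTR_RE.findall(attrs))
            gene_id = attr_map.get("gene_id")
            tx_id = attr_map.get("transcript_id")
            if not gene_id or not tx_id:
                raise GtfParseError(f"{path.name} line {lineno}: missing gene_id/transcript_id attribute")
            prev = meta.setdefault(tx_id, (gene_id, chrom, strand))
            if prev != (gene_id, chrom, strand):
                raise GtfParseError(
                    f"{path.name} line {lineno}: transcript {tx_id} has inconsistent gene/chrom/strand"
                )
            iv = (start - 1, end)  # to 0-based half-open
            (exons if feature == "exon" else cds).setdefault(tx_id, []).append(iv)
    models = []
    for tx_id, (gene_id, chrom, strand) in meta.items():
        if tx_id not in exons:
            raise ValidationError(f"transcript {tx_id} has CDS features but no exons")
        models.append(
            build_transcript(tx_id, gene_id, chrom, strand, exons[tx_id], cds.get(tx_id, ()))
        )
    return TranscriptCatalog.from_transcripts(models)


def write_gtf(catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write a catalog back to GTF (1-based inclusive), deterministically ordered."""
    lines = []
    for gene_id in sorted(catalog.genes):
        for tx_id in sorted(catalog.genes[gene_id]):
            m = catalog.transcripts[tx_id]
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = (m.exons[0][0] + 1, m.exons[-1][1])
            lines.append(f"{m.chrom}\tribosel\ttranscript\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t{attrs}")
            for a, b in m.exons:
                lines.append(f"{m.chrom}\tribosel\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}")
            for a, b in m.cds:
                lines.append(f"{m.chrom}\tribosel\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t{attrs}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# libraries and abundance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library: condition (A/B) × fraction (cytosolic/ribosome)."""

    library_id: str
    condition: str
    fraction: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(f"library {self.library_id}: fraction must be one of {FRACTIONS}")
        if self.total_mapped_reads < 1:
            raise ValidationError(f"library {self.library_id}: total_mapped_reads must be positive")


def check_library_design(specs: Sequence[LibrarySpec]) -> None:
    """Require unique (condition, fraction) pairs across libraries."""
    seen = set()
    for s in specs:
        key = (s.condition, s.fraction)
        if key in seen:
            raise ValidationError(f"duplicate library for condition={s.condition}, fraction={s.fraction}")
        seen.add(key)


@dataclass
class AbundanceTable:
    """Transcript × library matrices of estimated counts and FPKM.

    ``tx2gene`` links each transcript row to its gene for exact gene-level
    aggregation; ``lengths`` holds exonic transcript lengths in nucleotides.
    """

    counts: pd.DataFrame
    fpkm: pd.DataFrame
    tx2gene: pd.Series
    lengths: pd.Series
    specs: tuple[LibrarySpec, ...]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.fpkm.index) or not self.counts.columns.equals(self.fpkm.columns):
            raise ValidationError("counts and fpkm matrices must share shape and indices")
        if (self.counts.to_numpy() < 0).any() or (self.fpkm.to_numpy() < 0).any():
            raise ValidationError("counts and fpkm must be nonnegative")
        missing = self.counts.index.difference(self.tx2gene.index)
        if len(missing):
            raise ValidationError(f"transcripts missing from tx2gene mapping: {list(missing)[:5]}")
        lib_ids = [s.library_id for s in self.specs]
        if sorted(lib_ids) != sorted(self.counts.columns):
            raise ValidationError("library specs do not match table columns")

    def library_id(self, condition: str, fraction: str) -> str:
        for s in self.specs:
            if s.condition == condition and s.fraction == fraction:
                return s.library_id
        raise KeyError(f"no library with condition={condition}, fraction={fraction}")

    def spec(self, library_id: str) -> LibrarySpec:
        for s in self.specs:
            if s.library_id == library_id:
                return s
        raise KeyError(library_id)

    def gene_counts(self) -> pd.DataFrame:
        return self.counts.groupby(self.tx2gene.reindex(self.counts.index)).sum()

    def gene_fpkm(self) -> pd.DataFrame:
        return self.fpkm.groupby(self.tx2gene.reindex(self.fpkm.index)).sum()

    def gene_ids(self) -> list[str]:
        return sorted(self.tx2gene.reindex(self.counts.index).unique())


def read_quantification(
    path: str | Path,
    specs: Sequence[LibrarySpec],
    catalog: TranscriptCatalog | None = None,
) -> AbundanceTable:
    """Read the merged quantification TSV.

    Expected header: ``transcript_id, gene_id, length`` then per-library
    ``<library_id>_count`` and ``<library_id>_fpkm`` columns.  Transcripts in
    the catalog but absent from the file are filled with zeros (an assembler
    drops unexpressed isoforms; zero is the faithful reading).
    """
    df = pd.read_csv(path, sep="\t")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValidationError(f"duplicate transcript_id in quantification table: {dup}")
    df = df.set_index("transcript_id")
    for s in specs:
        for suffix in ("count", "fpkm"):
            col = f"{s.library_id}_{suffix}"
            if col not in df.columns:
                raise ValidationError(f"quantification table lacks column {col} for library {s.library_id}")
    if catalog is not None:
        missing = [t for t in catalog.transcripts if t not in df.index]
        if missing:
            fill = pd.DataFrame(0.0, index=pd.Index(missing, name="transcript_id"), columns=df.columns)
            fill["gene_id"] = [catalog.transcripts[t].gene_id for t in missing]
            fill["length"] = [catalog.transcripts[t].length for t in missing]
            df = pd.concat([df, fill])
    df = df.sort_index()
    lib_ids = [s.library_id for s in specs]
    counts = df[[f"{l}_count" for l in lib_ids]].astype(float)
    counts.columns = lib_ids
    fpkm = df[[f"{l}_fpkm" for l in lib_ids]].astype(float)
    fpkm.columns = lib_ids
    if (counts.to_numpy() < 0).any() or (fpkm.to_numpy() < 0).any():
        raise ValidationError("negative count or FPKM value in quantification table")
    return AbundanceTable(
        counts=counts,
        fpkm=fpkm,
        tx2gene=df["gene_id"].astype(str),
        lengths=df["length"].astype(float),
        specs=tuple(specs),
    )


def write_quantification(table: AbundanceTable, path: str | Path) -> None:
    """Inverse of :func:`read_quantification`; rows sorted by gene then transcript."""
    df = pd.DataFrame(
        {
            "transcript_id": table.counts.index,
            "gene_id": table.tx2gene.reindex(table.counts.index).to_numpy(),
            "length": table.lengths.reindex(table.counts.index).to_numpy(),
        }
    )
    for s in table.specs:
        df[f"{s.library_id}_count"] = table.counts[s.library_id].to_numpy()
        df[f"{s.library_id}_fpkm"] = table.fpkm[s.library_id].to_numpy()
    df = df.sort_values(["gene_id", "transcript_id"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: deterministic row order, floats at 6 significant digits."""
    if table is None:
        raise ValueError("table must not be None")
    df = table.copy()
    df.index = pd.RangeIndex(len(df))  # drop any named index so columns are unambiguous
    sort_cols = [c for c in ("gene_id", "transcript_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    collection: dict[str, dict] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {lineno}: expected term, description and at least one gene")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"GMT line {lineno}: gene set {term} is empty")
            collection[term] = {"description": desc, "genes": frozenset(genes)}
    return collection
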