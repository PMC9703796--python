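"""Genome-skimming SNP matrix construction and filtering.

Implements the post-mapping half of a skimming SNP pipeline: per-site
depth/quality/heterozygosity masking of variant calls, conversion of the
surviving calls into an aligned character matrix, most-common-base
consensus calling, missing-data column thresholds, invariant-site removal,
per-gene length filtering, reference coverage masking, and supermatrix
concatenation with a partition table.

Conventions (documented because off-by-one and boundary bugs are the
failure mode of this kind of code):

* Variant records are 1-based (VCF convention); interval sets
  (:class:`CoverageMap`, BED) are 0-based half-open.  Converters sit at
  every I/O boundary.
* The depth/quality boundaries *pass*: sites are deleted when coverage is
  strictly less than 4 or quality strictly less than 20.
* The missing-data column threshold is inclusive (a column with exactly
  40% missing survives ``max_missing=0.4``).
* Gap ``-`` counts as missing for the threshold and as a non-state for
  invariance.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = "N"
GAP = "-"
_BASES = ("A", "C", "G", "T")

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

__all__ = [
    "MISSING",
    "GAP",
    "SampleCall",
    "SiteRecord",
    "AlignmentMatrix",
    "CoverageMap",
    "filter_site",
    "sites_to_alignment",
    "consensus_sequence",
    "column_missing_fraction",
    "apply_missing_threshold",
    "remove_invariant_sites",
    "concatenate",
    "split_by_partitions",
    "mask_uncovered",
    "filter_genes_by_length",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "write_partitions",
    "write_bed",
    "read_bed",
]


# ---------------------------------------------------------------------------
# Site records and per-site filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at one site: genotype alleles, read depth, and an
    optional per-genotype quality."""

    alleles: tuple[str | None, str | None]
    depth: int
    genotype_quality: float | None = None

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError(f"negative read depth {self.depth}")
        for a in self.alleles:
            if a is not None and a not in _BASES:
                raise ValueError(f"allele must be one of A,C,G,T or None, got {a!r}")

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    @property
    def is_heterozygous(self) -> bool:
        return (not self.is_missing) and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class SiteRecord:
    """A VCF-like site: position, reference base, site-level quality, and
    per-sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    quality: float
    calls: Mapping[str, SampleCall]

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


def filter_site(
    record: SiteRecord,
    min_depth: int = 4,
    min_quality: float = 20.0,
    use_genotype_quality: bool = False,
    drop_site_on_het: bool = False,
) -> dict[str, str]:
    """Apply the three deletion rules to one site; return per-sample bases.

    A sample's base becomes missing ("N") when its depth is < ``min_depth``,
    when the quality is < ``min_quality``, or when the genotype is
    heterozygous; depth exactly 4 and quality exactly 20 pass.  Quality is
    the site-level score unless ``use_genotype_quality``.  With
    ``drop_site_on_het`` a single heterozygous sample masks the whole site.
    """
    out: dict[str, str] = {}
    any_het = any(c.is_heterozygous for c in record.calls.values())
    for sample, call in record.calls.items():
        qual = call.genotype_quality if use_genotype_quality else record.quality
        if call.is_missing:
            out[sample] = MISSING
        elif call.depth < min_depth:
            out[sample] = MISSING
        elif qual is None or qual < min_quality:
            out[sample] = MISSING
        elif call.is_heterozygous or (drop_site_on_het and any_het):
            out[sample] = MISSING
        else:
            out[sample] = call.alleles[0]
    return out


# ---------------------------------------------------------------------------
# Alignment matrix
# ---------------------------------------------------------------------------


@dataclass
class AlignmentMatrix:
    """Taxa x sites character matrix with an optional partition table.

    Partitions are (name, start, end), 1-based inclusive column ranges.
    """

    taxa: list[str]
    data: np.ndarray  # shape (n_taxa, n_sites), dtype '<U1'
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be a (n_taxa, n_sites) matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        for name, start, end in self.partitions:
            if not (1 <= start <= end <= self.n_sites):
                raise ValueError(f"partition {name} range ({start}, {end}) out of bounds")

    @classmethod
    def from_rows(cls, rows: Mapping[str, str] | Iterable[tuple[str, str]],
                  partitions=None) -> "AlignmentMatrix":
        items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
        taxa = [t for t, _ in items]
        seqs = [s.upper() for _, s in items]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("all rows must have equal length")
        data = np.array([list(s) for s in seqs], dtype="<U1") if seqs else np.empty((0, 0), "<U1")
        return cls(taxa, data, partitions or [])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def column(self, j: int) -> list[str]:
        if not (0 <= j < self.n_sites):
            raise IndexError(f"column {j} out of range [0, {self.n_sites})")
        return list(self.data[:, j])

    def rows(self) -> dict[str, str]:
        return {t: "".join(r) for t, r in zip(self.taxa, self.data)}


def sites_to_alignment(
    records: Sequence[SiteRecord],
    samples: Sequence[str],
    **filter_kwargs,
) -> AlignmentMatrix:
    """One alignment column per record, in order, after per-site filtering.

    Records must already be sorted by (chrom, position).
    """
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, position)")
    samples = list(samples)
    data = np.full((len(samples), len(records)), MISSING, dtype="<U1")
    for j, rec in enumerate(records):
        masked = filter_site(rec, **filter_kwargs)
        for i, s in enumerate(samples):
            data[i, j] = masked.get(s, MISSING)
    return AlignmentMatrix(samples, data)


def consensus_sequence(site_counts: Sequence[Mapping[str, int]]) -> str:
    """Most-common-base consensus.

    Per site the plurality base wins; ties produce the IUPAC ambiguity code
    of the tied bases; a site with no observations is "N".
    """
    out = []
    for counts in site_counts:
        counts = {b: c for b, c in counts.items() if c > 0}
        if not counts:
            out.append(MISSING)
            continue
        best = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == best)
        out.append(IUPAC[tied])
    return "".join(out)


# ---------------------------------------------------------------------------
# Column filters
# ---------------------------------------------------------------------------


def _missing_mask(matrix: AlignmentMatrix) -> np.ndarray:
    return (matrix.data == MISSING) | (matrix.data == GAP)


def column_missing_fraction(matrix: AlignmentMatrix, column: int) -> float:
    """(missing + gap) / taxon count for one 0-based column."""
    if not (0 <= column < matrix.n_sites):
        raise IndexError(f"column {column} out of range [0, {matrix.n_sites})")
    col = matrix.data[:, column]
    return float(((col == MISSING) | (col == GAP)).mean())


def _remap_partitions(partitions, keep: np.ndarray):
    """Rebuild a partition table after dropping columns (keep is boolean)."""
    if not partitions:
        return []
    new_pos = np.cumsum(keep)  # 1-based new index of each kept column
    out = []
    for name, start, end in partitions:
        seg = keep[start - 1 : end]
        kept = int(seg.sum())
        if kept == 0:
            continue
        first = int(np.argmax(seg))  # first kept column within the segment
        new_start = int(new_pos[start - 1 + first])
        out.append((name, new_start, new_start + kept - 1))
    return out


def apply_missing_threshold(matrix: AlignmentMatrix, max_missing: float) -> AlignmentMatrix:
    """Keep columns whose missing fraction is <= ``max_missing``.

    Column order is preserved and the partition table remapped.  The
    boundary is inclusive: a threshold names a tolerated level.
    """
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be within [0, 1]")
    frac = _missing_mask(matrix).mean(axis=0)
    keep = frac <= max_missing + 1e-12
    return AlignmentMatrix(
        list(matrix.taxa), matrix.data[:, keep], _remap_partitions(matrix.partitions, keep)
    )


def remove_invariant_sites(matrix: AlignmentMatrix) -> tuple[AlignmentMatrix, dict[str, int]]:
    """Keep columns with >= 2 distinct states among A, C, G, T.

    Missing and gap characters do not count as states; a column that is
    constant over its called bases is invariant however much missing data
    it carries.  Returns the filtered matrix and a kept/removed report.
    """
    keep = np.zeros(matrix.n_sites, dtype=bool)
    base_counts = np.stack([(matrix.data == b).any(axis=0) for b in _BASES])
    keep = base_counts.sum(axis=0) >= 2
    out = AlignmentMatrix(
        list(matrix.taxa), matrix.data[:, keep], _remap_partitions(matrix.partitions, keep)
    )
    return out, {"kept": int(keep.sum()), "removed": int((~keep).sum())}


def concatenate(
    matrices: Sequence[AlignmentMatrix] | Mapping[str, AlignmentMatrix],
    taxa: Sequence[str] | None = None,
) -> AlignmentMatrix:
    """Concatenate gene alignments into a supermatrix.

    Columns are appended left-to-right in input order; a taxon absent from
    a gene is padded with "N" over that gene's span; the partition table
    records each gene's 1-based inclusive range.
    """
    if isinstance(matrices, Mapping):
        named = list(matrices.items())
    else:
        named = [(f"gene{i + 1}", m) for i, m in enumerate(matrices)]
    if not named:
        raise ValueError("concatenate needs at least one matrix")
    if taxa is None:
        seen: dict[str, None] = {}
        for _, m in named:
            for t in m.taxa:
                seen.setdefault(t, None)
        taxa = list(seen)
    taxa = list(taxa)
    total = sum(m.n_sites for _, m in named)
    data = np.full((len(taxa), total), MISSING, dtype="<U1")
    partitions = []
    offset = 0
    for name, m in named:
        idx = {t: i for i, t in enumerate(m.taxa)}
        for i, t in enumerate(taxa):
            if t in idx:
                data[i, offset : offset + m.n_sites] = m.data[idx[t]]
        if m.n_sites:
            partitions.append((name, offset + 1, offset + m.n_sites))
        offset += m.n_sites
    return AlignmentMatrix(taxa, data, partitions)


def split_by_partitions(matrix: AlignmentMatrix) -> dict[str, AlignmentMatrix]:
    """Inverse of :func:`concatenate` for a partitioned supermatrix."""
    out = {}
    for name, start, end in matrix.partitions:
        out[name] = AlignmentMatrix(list(matrix.taxa), matrix.data[:, start - 1 : end])
    return out


def filter_genes_by_length(
    alignments: Mapping[str, AlignmentMatrix], min_length: int
) -> dict[str, AlignmentMatrix]:
    """Keep alignments at least ``min_length`` columns wide (inclusive)."""
    return {n: m for n, m in alignments.items() if m.n_sites >= min_length}


# ---------------------------------------------------------------------------
# Coverage masking
# ---------------------------------------------------------------------------


@dataclass
class CoverageMap:
    """Per-sample covered intervals on a reference, 0-based half-open."""

    sample: str
    intervals: list[tuple[int, int]]

    def __post_init__(self):
        self.intervals = _normalize(self.intervals)


def _normalize(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def mask_uncovered(
    reference_length: int, maps: Sequence[CoverageMap]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Regions covered by at least one sample (kept) and their complement
    (masked), both as sorted, normalized 0-based half-open intervals."""
    if not maps:
        raise ValueError("mask_uncovered needs at least one coverage map")
    all_ivs = []
    for m in maps:
        for a, b in m.intervals:
            if a < 0 or b > reference_length:
                raise ValueError(
                    f"interval [{a}, {b}) outside reference bounds [0, {reference_length})"
                )
            all_ivs.append((a, b))
    kept = _normalize(all_ivs)
    masked = []
    prev = 0
    for a, b in kept:
        if a > prev:
            masked.append((prev, a))
        prev = b
    if prev < reference_length:
        masked.append((prev, reference_length))
    return kept, masked


# ---------------------------------------------------------------------------
# I/O: VCF (via pysam), FASTA (via Biopython), partitions, BED
# ---------------------------------------------------------------------------


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_vcf(path) -> tuple[list[str], list[SiteRecord]]:
    """Read a VCF (v4.x, plain or bgzipped) into :class:`SiteRecord` rows.

    Uses the FORMAT GT and DP fields and the site-level QUAL column; GQ is
    carried along when present.
    """
    import pysam

    records: list[SiteRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alleles = rec.alleles  # (ref, alt1, ...)
            calls = {}
            for s in samples:
                sd = rec.samples[s]
                gt = sd.get("GT", (None, None))
                if gt is None:
                    gt = (None, None)
                if len(gt) == 1:
                    gt = (gt[0], gt[0])
                pair = tuple(
                    alleles[i] if (i is not None and alleles[i] in _BASES) else None
                    for i in gt
                )
                depth = sd.get("DP", 0)
                gq = sd.get("GQ", None)
                calls[s] = SampleCall(pair, int(depth) if depth is not None else 0,
                                      float(gq) if gq is not None else None)
            records.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    calls=calls,
                )
            )
    return samples, records


def write_vcf(path, samples: Sequence[str], records: Sequence[SiteRecord],
              contigs: Mapping[str, int] | None = None) -> None:
    """Write records as minimal VCF v4.2 text (GT:DP[:GQ] per sample)."""
    has_gq = any(
        c.genotype_quality is not None for r in records for c in r.calls.values()
    )
    fmt = "GT:DP:GQ" if has_gq else "GT:DP"
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            alts: list[str] = []
            for call in rec.calls.values():
                for a in call.alleles:
                    if a is not None and a != rec.ref and a not in alts:
                        alts.append(a)
            allele_idx = {rec.ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            cols = [rec.chrom, str(rec.pos), ".", rec.ref, ",".join(alts) or ".",
                    f"{rec.quality:g}", "PASS", ".", fmt]
            for s in samples:
                call = rec.calls.get(s)
                if call is None or call.is_missing:
                    gt = "./."
                else:
                    gt = "/".join(str(allele_idx[a]) for a in call.alleles)
                parts = [gt, str(call.depth if call else 0)]
                if has_gq:
                    gq = call.genotype_quality if call else None
                    parts.append(f"{gq:g}" if gq is not None else ".")
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")


def read_fasta(path) -> AlignmentMatrix:
    from Bio import SeqIO

    with _open_text(path) as fh:
        rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    return AlignmentMatrix.from_rows(rows)


def write_fasta(path, matrix: AlignmentMatrix, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for taxon, seq in matrix.rows().items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_partitions(path, matrix: AlignmentMatrix, datatype: str = "DNA") -> None:
    """RAxML-style partition file: ``DNA, name = start-end``."""
    with _open_text(path, "wt") as fh:
        for name, start, end in matrix.partitions:
            fh.write(f"{datatype}, {name} = {start}-{end}\n")


def write_bed(path, chrom: str, intervals: Sequence[tuple[int, int]]) -> None:
    with _open_text(path, "wt") as fh:
        for a, b in intervals:
            fh.write(f"{chrom}\t{a}\t{b}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, a, b = line.split("\t")[:3]
            out.append((chrom, int(a), int(b)))
    return out
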