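"""Domain types and I/O for gene annotations, coverage tracks, counts and promoters.

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive) is
converted on read and write; BED is already 0-based half-open. The promoter
window used throughout the project is the region from 50 bp to 10 bp upstream
of the TSS, inclusive on both ends (41 bp), oriented 5'->3' of the gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "CountMatrix",
    "PromoterWindow",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "read_counts",
    "read_sample_sheet",
    "extract_promoter_window",
    "reverse_complement",
]

CONDITIONS = ("control", "dsBRM", "dsBRM_WT", "dsBRM_K804R")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented genomic interval.

    ``start``/``end`` are 0-based half-open; ``tss`` is the first transcribed
    base (``start`` on +, ``end - 1`` on -) and ``tes`` the last (the
    cleavage/polyadenylation terminus).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-base non-negative signal over named reference sequences."""

    def __init__(self, chrom_sizes: Mapping[str, int]) -> None:
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.data: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=float) for c, n in self.chrom_sizes.items()
        }

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def validate(self) -> None:
        for chrom, vec in self.data.items():
            if vec.shape != (self.chrom_sizes[chrom],):
                raise ValueError(f"{chrom}: vector length != declared chromosome length")
            if np.any(vec < 0) or not np.all(np.isfinite(vec)):
                raise ValueError(f"{chrom}: coverage must be finite and >= 0")

    def region_mean(self, chrom: str, start: int, end: int, clip: bool = True) -> float:
        """Mean signal over [start, end); optionally clipped to the chromosome."""
        n = self.chrom_sizes[chrom]
        if clip:
            start, end = max(0, start), min(n, end)
        if not (0 <= start < end <= n):
            raise ValueError(f"empty or out-of-bounds region {chrom}:[{start},{end})")
        return float(self.data[chrom][start:end].mean())

    def global_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.data.values())
        nbp = sum(self.chrom_sizes.values())
        return total / nbp

    def scaled_to_mean(self, target: float = 1.0) -> "CoverageTrack":
        """A copy rescaled so the genome-wide mean equals ``target``."""
        m = self.global_mean()
        if m <= 0:
            raise ValueError("cannot rescale an all-zero track")
        out = CoverageTrack(self.chrom_sizes)
        for c in self.data:
            out.data[c] = self.data[c] * (target / m)
        return out

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if self.chrom_sizes != other.chrom_sizes:
            raise ValueError("tracks defined on different chromosome sets")
        out = CoverageTrack(self.chrom_sizes)
        for c in self.data:
            out.data[c] = self.data[c] + other.data[c]
        return out


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus a sample sheet (condition, replicate)."""

    counts: pd.DataFrame  # index gene_id, columns sample ids
    samples: pd.DataFrame  # index sample_id, columns: condition, replicate

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gene ids in count matrix")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(f"count columns and sample sheet disagree: {sorted(missing)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected one of {CONDITIONS}")

    def samples_for(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented promoter sequence for one gene (or one alternative TSS)."""

    gene_id: str
    sequence: str
    clipped: bool = False


# ---------------------------------------------------------------------------
# Annotation I/O


def _check_unique(genes: Sequence[GeneModel], path) -> list[GeneModel]:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return list(genes)


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED (6+ columns), by file extension.

    GFF3 keeps only ``gene`` features and converts 1-based inclusive
    coordinates to the internal 0-based half-open convention.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path)
    if suffix in (".bed", ".bed6", ".bed12"):
        return _read_bed(path)
    raise AnnotationError(f"{path}: unrecognized annotation extension {suffix!r}")


def _read_gff3(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "gene":
                continue
            m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
            if m is None:
                raise AnnotationError(f"{path}:{lineno}: gene feature without ID attribute")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                genes.append(GeneModel(m.group(1), chrom, start_i - 1, end_i, strand))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return _check_unique(genes, path)


def _read_bed(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"{path}:{lineno}: need >= 6 BED columns (strand required)")
            chrom, start, end, name, _, strand = fields[:6]
            try:
                genes.append(GeneModel(name, chrom, int(start), int(end), strand))
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return _check_unique(genes, path)


def write_annotation(genes: Iterable[GeneModel], path: str | Path, header: str | None = None) -> None:
    """Write gene models as GFF3 or BED6, chosen by the file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    with open(path, "w") as fh:
        if suffix in (".gff", ".gff3"):
            fh.write("##gff-version 3\n")
            if header:
                fh.write(f"# {header}\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tbrmmode\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
        elif suffix in (".bed", ".bed6"):
            if header:
                fh.write(f"# {header}\n")
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise AnnotationError(f"{path}: unrecognized annotation extension {suffix!r}")


# ---------------------------------------------------------------------------
# Coverage I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, n = line.split()[:2]
            sizes[chrom] = int(n)
    return sizes


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    overlap: str = "error",
) -> CoverageTrack:
    """Expand a bedGraph into a per-base CoverageTrack.

    Bases not covered by any interval are 0. Overlapping intervals raise by
    default; ``overlap="last"`` lets later lines overwrite earlier ones.
    """
    if overlap not in ("error", "last"):
        raise ValueError("overlap must be 'error' or 'last'")
    track = CoverageTrack(chrom_sizes)
    covered = {c: np.zeros(n, dtype=bool) for c, n in track.chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in track.chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > track.chrom_sizes[chrom] or start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside {chrom} "
                    f"(length {track.chrom_sizes[chrom]})"
                )
            if overlap == "error" and covered[chrom][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping interval on {chrom}")
            track.data[chrom][start:end] = value
            covered[chrom][start:end] = True
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path, header: str | None = None) -> None:
    """Run-length encode a CoverageTrack back to bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for chrom in track.data:
            vec = track.data[chrom]
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Counts I/O


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a gene x sample counts TSV plus a sample sheet TSV.

    Counts TSV: first column gene_id, header row of sample ids. Sample sheet:
    columns sample_id, condition, replicate.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    samples = read_sample_sheet(samples_path)
    counts = counts[list(samples.index)]
    return CountMatrix(counts=counts.astype(np.int64), samples=samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "replicate"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return samples.set_index("sample_id")


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path,
                 header: str | None = None) -> None:
    with open(counts_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        cm.counts.rename_axis("gene_id").to_csv(fh, sep="\t")
    with open(samples_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        cm.samples.rename_axis("sample_id").to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Promoter windows


def extract_promoter_window(
    gene: GeneModel,
    genome,
    up: int = 50,
    down: int = 10,
    window_id: str | None = None,
) -> PromoterWindow:
    """Extract the [TSS-up, TSS-down] window (inclusive ends), gene-oriented.

    ``genome`` is a mapping chrom -> sequence (a ``pyfaidx.Fasta`` or a plain
    dict of strings). For - strand genes the mirrored downstream window is
    taken and reverse-complemented so the result reads 5'->3' of the gene.
    Windows running off the chromosome are clipped and flagged.
    """
    if up < down:
        raise ValueError("require up >= down for an upstream window")
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} absent from genome")
    ref = genome[gene.chrom]
    chrom_len = len(ref)
    if gene.strand == "+":
        lo, hi = gene.tss - up, gene.tss - down + 1
    else:
        lo, hi = gene.tss + down, gene.tss + up + 1
    clipped_lo, clipped_hi = max(0, lo), min(chrom_len, hi)
    clipped = (clipped_lo, clipped_hi) != (lo, hi)
    seq = str(ref[clipped_lo:clipped_hi]).upper()
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return PromoterWindow(
        gene_id=window_id or gene.gene_id, sequence=seq, clipped=clipped
    )
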