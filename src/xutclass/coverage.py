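"""Strand-specific per-nucleotide coverage from aligned reads.

Nascent-transcription sequencing reports the position of elongating RNA
polymerase, so coverage is kept per strand and (by default) each read is
collapsed to a single point: the 3' end of the nascent transcript, the
standard proxy for the polymerase active site. Full-read coverage and
5'-end assignment are available as alternative modes.

Coverage values are raw tag counts until :func:`normalize_to_library`
scales them to a common library size (the "tag/nt" scale used for
metagene profiles and feature quantification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, NamedTuple, Tuple

import numpy as np

from .annotations import FeatureAnnotation

__all__ = [
    "AlignedRead",
    "StrandedCoverage",
    "coverage_from_alignments",
    "normalize_to_library",
    "feature_signal",
    "write_bedgraph",
    "read_bedgraph",
    "read_sam_alignments",
    "read_bed_alignments",
    "ASSIGNMENT_MODES",
]

ASSIGNMENT_MODES = ("point_3prime", "point_5prime", "full_read")


class AlignedRead(NamedTuple):
    """Minimal aligned-read record: reference interval + strand."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str


@dataclass
class StrandedCoverage:
    """Per-chromosome, per-strand vectors of per-nucleotide tag counts.

    Attributes
    ----------
    plus, minus:
        chrom -> float vector of chromosome length.
    library_size:
        Total tags assigned (raw scale).
    normalized:
        False while values are raw tags; True after scaling to a target
        library size.
    """

    plus: Dict[str, np.ndarray]
    minus: Dict[str, np.ndarray]
    library_size: float
    normalized: bool = False

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int]) -> "StrandedCoverage":
        return cls(
            plus={c: np.zeros(n) for c, n in chrom_sizes.items()},
            minus={c: np.zeros(n) for c, n in chrom_sizes.items()},
            library_size=0.0,
        )

    def strand(self, strand: str) -> Dict[str, np.ndarray]:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.plus.items()}

    def total(self) -> float:
        return float(
            sum(v.sum() for v in self.plus.values())
            + sum(v.sum() for v in self.minus.values())
        )


def coverage_from_alignments(
    alignments: Iterable[AlignedRead],
    chrom_sizes: Mapping[str, int],
    assignment_mode: str = "point_3prime",
) -> StrandedCoverage:
    """Accumulate stranded coverage from aligned read intervals.

    In the point modes each read increments exactly one genomic position:
    the 3'-most (``point_3prime``, default: RNAPII position in NET-Seq) or
    5'-most (``point_5prime``) base of the read *in transcript
    orientation* — so for a minus-strand read the 5' end is the highest
    genomic coordinate. In ``full_read`` mode every covered base is
    incremented. ``library_size`` is the number of reads assigned.

    Raises
    ------
    ValueError
        If a read lies outside its chromosome (the message names the
        record) or the mode is unknown.
    """
    if assignment_mode not in ASSIGNMENT_MODES:
        raise ValueError(
            f"unknown assignment_mode {assignment_mode!r}; expected one of {ASSIGNMENT_MODES}"
        )
    cov = StrandedCoverage.zeros(chrom_sizes)
    n_reads = 0
    for read in alignments:
        if read.chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome: {read}")
        size = chrom_sizes[read.chrom]
        if read.start < 0 or read.end > size or read.start >= read.end:
            raise ValueError(f"read beyond chromosome bounds: {read}")
        vec = cov.strand(read.strand)[read.chrom]
        if assignment_mode == "full_read":
            vec[read.start : read.end] += 1.0
        else:
            want_5prime = assignment_mode == "point_5prime"
            if (read.strand == "+") == want_5prime:
                pos = read.start
            else:
                pos = read.end - 1
            vec[pos] += 1.0
        n_reads += 1
    cov.library_size = float(n_reads)
    return cov


def normalize_to_library(cov: StrandedCoverage, target: float) -> StrandedCoverage:
    """Scale a raw coverage to a common library size (tags-per-position).

    Every value is multiplied by ``target / library_size``. Raises on an
    empty library or an already-normalized input.
    """
    if cov.normalized:
        raise ValueError("coverage is already normalized")
    if cov.library_size <= 0:
        raise ValueError("cannot normalize a coverage with library_size 0")
    scale = target / cov.library_size
    return StrandedCoverage(
        plus={c: v * scale for c, v in cov.plus.items()},
        minus={c: v * scale for c, v in cov.minus.items()},
        library_size=cov.library_size,
        normalized=True,
    )


def feature_signal(
    cov: StrandedCoverage,
    f: FeatureAnnotation,
    orientation: str = "sense",
) -> Tuple[float, float]:
    """Mean tag/nt and total tags over a feature's interval.

    ``orientation="sense"`` sums the feature's own strand,
    ``"antisense"`` the opposite strand. Returns ``(mean, total)``.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be 'sense' or 'antisense', got {orientation!r}")
    iv = f.interval
    strand = iv.strand if orientation == "sense" else ("-" if iv.strand == "+" else "+")
    vectors = cov.strand(strand)
    if iv.chrom not in vectors:
        raise ValueError(f"unknown chromosome {iv.chrom!r} for feature {f.id!r}")
    vec = vectors[iv.chrom]
    if iv.end > len(vec):
        raise ValueError(f"feature {f.id!r} extends beyond chromosome {iv.chrom!r}")
    total = float(vec[iv.start : iv.end].sum())
    return total / len(iv), total


def write_bedgraph(cov: StrandedCoverage, strand: str, path: str | Path) -> None:
    """Write one strand of a coverage as bedGraph (0-based half-open runs).

    Zero runs are omitted, so an all-zero coverage yields an empty body.
    """
    vectors = cov.strand(strand)
    with open(path, "w") as fh:
        for chrom in sorted(vectors):
            vec = vectors[chrom]
            # run-length encode: boundaries where the value changes
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                val = vec[s]
                if val != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(val)}\n")


def _fmt(val: float) -> str:
    return str(int(val)) if float(val).is_integer() else repr(float(val))


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int]
) -> Dict[str, np.ndarray]:
    """Read a bedGraph file back into per-chromosome vectors."""
    out = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, val = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom not in out:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            out[chrom][start:end] = val
    return out


def read_sam_alignments(path: str | Path) -> Iterator[AlignedRead]:
    """Yield mapped, primary alignments from a SAM/BAM file via pysam.

    The read strand follows the FLAG's reverse bit. Unmapped, secondary
    and supplementary records are skipped.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield AlignedRead(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
            )


def read_bed_alignments(path: str | Path) -> Iterator[AlignedRead]:
    """Yield reads from a 6-column BED file (chrom start end name score strand)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}: line {lineno}: need 6 BED columns")
            yield AlignedRead(cols[0], int(cols[1]), int(cols[2]), cols[5])
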