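"""Genomic annotations and strand-aware antisense pairing.

Features (protein-coding genes, XUTs, sn/snoRNAs) live on a genome as
strand-aware intervals. Internally all coordinates are 0-based half-open;
GFF3 input/output converts from/to the format's 1-based inclusive
convention at the boundary.

The central operation is :func:`antisense_pairs`: a gene "has an asXUT"
when at least one XUT annotation overlaps it on the opposite strand by at
least ``min_overlap`` nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

__all__ = [
    "GenomicInterval",
    "FeatureAnnotation",
    "GffParseError",
    "read_gff",
    "write_gff",
    "tss_of",
    "antisense_pairs",
    "overlap_length",
    "write_pairing_tsv",
    "DEFAULT_KIND_MAP",
]

VALID_STRANDS = frozenset({"+", "-"})

#: feature kinds recognised downstream
KINDS = ("mRNA", "XUT", "snRNA_snoRNA", "other")

#: default mapping from GFF feature type (column 3) to annotation kind
DEFAULT_KIND_MAP: Mapping[str, str] = {
    "mRNA": "mRNA",
    "gene": "mRNA",
    "protein_coding_gene": "mRNA",
    "XUT": "XUT",
    "lncRNA": "XUT",
    "snRNA": "snRNA_snoRNA",
    "snoRNA": "snRNA_snoRNA",
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureAnnotation:
    """A named feature with a kind controlling downstream eligibility.

    Only ``kind="mRNA"`` features are classified into classes 1-4; only
    ``kind="XUT"`` features can form antisense pairs.
    """

    id: str
    interval: GenomicInterval
    kind: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")


class GffParseError(ValueError):
    """Malformed GFF input; message names the offending line."""


def tss_of(f: FeatureAnnotation) -> int:
    """Transcription start site of a feature (strand-dependent interval end).

    Returns ``start`` on the plus strand and ``end - 1`` on the minus
    strand, i.e. the first transcribed base in both cases.
    """
    iv = f.interval
    return iv.start if iv.strand == "+" else iv.end - 1


def read_gff(
    path: str | Path,
    kind_map: Mapping[str, str] | None = None,
) -> List[FeatureAnnotation]:
    """Read a GFF3 file into a list of :class:`FeatureAnnotation`.

    Coordinates are converted from GFF's 1-based inclusive convention to
    0-based half-open. Feature kind is inferred from column 3 via
    ``kind_map`` (default :data:`DEFAULT_KIND_MAP`); unmapped types become
    ``"other"``. The feature id is the ``ID=`` attribute, falling back to
    ``Name=``.

    Raises
    ------
    GffParseError
        On a malformed line (naming its line number), an unknown strand
        symbol, or a duplicate feature id.
    """
    kind_map = DEFAULT_KIND_MAP if kind_map is None else kind_map
    feats: List[FeatureAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in VALID_STRANDS:
                raise GffParseError(f"line {lineno}: unknown strand symbol {strand!r}")
            if start1 < 1 or end1 < start1:
                raise GffParseError(
                    f"line {lineno}: invalid 1-based coordinates {start1}..{end1}"
                )
            attr_d = _parse_attributes(attrs)
            fid = attr_d.get("ID") or attr_d.get("Name")
            if fid is None:
                raise GffParseError(f"line {lineno}: feature without ID/Name attribute")
            if fid in seen:
                raise GffParseError(f"line {lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            feats.append(
                FeatureAnnotation(
                    id=fid,
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                    kind=kind_map.get(ftype, "other"),
                )
            )
    return feats


def _parse_attributes(attrs: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


# GFF feature type written per kind on output
_KIND_TO_TYPE = {"mRNA": "mRNA", "XUT": "XUT", "snRNA_snoRNA": "snRNA", "other": "region"}


def write_gff(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive), sorted by position."""
    feats = sorted(features, key=lambda f: (f.interval.chrom, f.interval.start, f.id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "xutclass",
                        _KIND_TO_TYPE[f.kind],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={f.id}",
                    ]
                )
                + "\n"
            )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint
    or on different chromosomes); strands are ignored here."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def antisense_pairs(
    genes: Iterable[FeatureAnnotation],
    xuts: Iterable[FeatureAnnotation],
    min_overlap: int = 1,
) -> Dict[str, List[str]]:
    """Pair each gene with the XUTs overlapping it on the opposite strand.

    A gene ``g`` is paired with XUT ``x`` iff they share a chromosome, lie
    on opposite strands, and their intervals intersect by at least
    ``min_overlap`` nucleotides. Pairing is many-to-many; genes with no
    partner are absent from the returned mapping.

    Parameters
    ----------
    min_overlap:
        Minimum overlap in nucleotides, >= 1. Default 1 (any overlap).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    xut_by_chrom: Dict[str, List[FeatureAnnotation]] = {}
    for x in xuts:
        xut_by_chrom.setdefault(x.interval.chrom, []).append(x)
    pairs: Dict[str, List[str]] = {}
    for g in genes:
        hits = [
            x.id
            for x in xut_by_chrom.get(g.interval.chrom, ())
            if x.interval.strand != g.interval.strand
            and overlap_length(g.interval, x.interval) >= min_overlap
        ]
        if hits:
            pairs[g.id] = sorted(hits)
    return pairs


def write_pairing_tsv(
    pairs: Mapping[str, List[str]],
    genes: Iterable[FeatureAnnotation],
    xuts: Iterable[FeatureAnnotation],
    path: str | Path,
) -> None:
    """Write the pairing table as TSV: gene_id, xut_id, overlap_nt."""
    gene_d = {g.id: g for g in genes}
    xut_d = {x.id: x for x in xuts}
    with open(path, "w") as fh:
        fh.write("gene_id\txut_id\toverlap_nt\n")
        for gid in sorted(pairs):
            for xid in pairs[gid]:
                ov = overlap_length(gene_d[gid].interval, xut_d[xid].interval)
                fh.write(f"{gid}\t{xid}\t{ov}\n")
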