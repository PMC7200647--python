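"""Coding-SNV classification: synonymous / nonsynonymous / stop-gain / stop-loss.

Minimal SNV-in-CDS annotator under the standard genetic code.  A CDS is a set
of 0-based half-open genomic intervals in transcription order; the spliced,
strand-corrected CDS sequence is supplied separately (from a reference CDS
FASTA).  Minus-strand variants are complemented before codon lookup, so
classification is invariant under the strand convention.  Start-loss changes
are reported as nonsynonymous (no separate category is used).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genotypes import Site

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CATEGORIES = ("synonymous", "nonsynonymous", "stopgain", "stoploss")


@dataclass(frozen=True)
class CdsAnnotation:
    """One transcript's CDS as intervals on the genome.

    `cds_intervals` are 0-based half-open and listed in transcription order
    (ascending start for '+', descending for '-').  `frame_offset` is the
    number of leading bases before the first complete codon.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0..2")
        ivals = self.cds_intervals
        if any(e <= s for s, e in ivals):
            raise ValueError("empty or inverted CDS interval")
        genomic = sorted(ivals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.transcript_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(ivals) != expected:
            raise ValueError("cds_intervals not in transcription order")
        if (self.cds_length - self.frame_offset) % 3 != 0:
            raise ValueError("CDS length not divisible by 3 after frame offset")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_index(self, pos: int) -> int:
        """Map a 1-based genomic position to its 0-based CDS coordinate."""
        pos0 = pos - 1
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos0 < end:
                within = (pos0 - start) if self.strand == "+" else (end - 1 - pos0)
                return offset + within
            offset += end - start
        raise ValueError(f"non-coding: position {pos} outside CDS of {self.transcript_id}")


@dataclass(frozen=True)
class VariantEffect:
    category: str
    ref_codon: str
    alt_codon: str
    aa_ref: str
    aa_alt: str


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=_STANDARD))


def classify_coding_snv(
    annotation: CdsAnnotation, cds_sequence: str, site: Site, alt: str
) -> VariantEffect:
    """Effect of substituting `alt` at `site` within an annotated CDS."""
    if site.chrom != annotation.chrom:
        raise ValueError("non-coding: site on a different chromosome")
    cds_sequence = cds_sequence.upper()
    if len(cds_sequence) != annotation.cds_length:
        raise ValueError("cds_sequence length does not match annotation")
    idx = annotation.cds_index(site.pos)
    ref_base = site.ref if annotation.strand == "+" else site.ref.translate(_COMPLEMENT)
    alt_base = alt if annotation.strand == "+" else alt.translate(_COMPLEMENT)
    if cds_sequence[idx] != ref_base:
        raise ValueError(
            f"reference mismatch at CDS index {idx}: sequence has "
            f"{cds_sequence[idx]}, site implies {ref_base}"
        )
    if idx < annotation.frame_offset:
        raise ValueError("position falls in the incomplete leading codon")
    codon_start = annotation.frame_offset + 3 * ((idx - annotation.frame_offset) // 3)
    ref_codon = cds_sequence[codon_start : codon_start + 3]
    within = idx - codon_start
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    aa_ref, aa_alt = _translate(ref_codon), _translate(alt_codon)
    if aa_ref == aa_alt:
        category = "synonymous"
    elif aa_alt == "*":
        category = "stopgain"
    elif aa_ref == "*":
        category = "stoploss"
    else:
        category = "nonsynonymous"
    return VariantEffect(category, ref_codon, alt_codon, aa_ref, aa_alt)


# ---------------------------------------------------------------------------
# BED I/O


def _transcription_order(
    intervals: list[tuple[int, int]], strand: str
) -> tuple[tuple[int, int], ...]:
    ordered = sorted(intervals)
    return tuple(ordered if strand == "+" else ordered[::-1])


def read_bed_cds(path: str | os.PathLike, dialect: str = "bed12") -> list[CdsAnnotation]:
    """Read CDS annotations from BED12 (blocks = CDS chunks) or BED6-per-exon."""
    if dialect not in ("bed12", "bed6"):
        raise ValueError("dialect must be 'bed12' or 'bed6'")
    annotations: list[CdsAnnotation] = []
    if dialect == "bed12":
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"{path}:{line_no}: BED12 needs 12 columns")
                chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                    raise ValueError(f"{path}:{line_no}: block count mismatch")
                ivals = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
                annotations.append(
                    CdsAnnotation(name, name, chrom, strand, _transcription_order(ivals, strand))
                )
    else:
        grouped: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"{path}:{line_no}: BED6 needs 6 columns")
                chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
                entry = grouped.setdefault(name, (chrom, strand, []))
                if entry[0] != chrom or entry[1] != strand:
                    raise ValueError(f"inconsistent chrom/strand for transcript {name}")
                entry[2].append((start, end))
        for name, (chrom, strand, ivals) in grouped.items():
            annotations.append(
                CdsAnnotation(name, name, chrom, strand, _transcription_order(ivals, strand))
            )
    return annotations


def write_bed_cds(
    annotations: Iterable[CdsAnnotation], path: str | os.PathLike
) -> None:
    """Write annotations as BED12 (one line per transcript, blocks = CDS)."""
    with open(path, "w") as fh:
        for ann in annotations:
            genomic = sorted(ann.cds_intervals)
            start, end = genomic[0][0], genomic[-1][1]
            sizes = ",".join(str(e - s) for s, e in genomic)
            offsets = ",".join(str(s - start) for s, _ in genomic)
            fh.write(
                "\t".join(
                    [
                        ann.chrom,
                        str(start),
                        str(end),
                        ann.transcript_id,
                        "0",
                        ann.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(genomic)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def effect_counts(
    matrix,
    annotations: Sequence[CdsAnnotation],
    cds_sequences: dict[str, str],
):
    """Per-strain counts of coding effects (one row per strain).

    Classifies every homozygous non-reference SNV falling inside an annotated
    CDS; a variant inside the CDS of several transcripts is counted once per
    strain per category occurrence using the first annotation that contains
    it (transcript order as supplied).  Returns a pandas DataFrame with
    columns strain, synonymous, nonsynonymous, stopgain, stoploss.
    """
    import pandas as pd

    from .genotypes import homozygous_variant_set

    by_chrom: dict[str, list[CdsAnnotation]] = {}
    for ann in annotations:
        by_chrom.setdefault(ann.chrom, []).append(ann)

    def locate(chrom: str, pos: int) -> CdsAnnotation | None:
        for ann in by_chrom.get(chrom, []):
            if any(s <= pos - 1 < e for s, e in ann.cds_intervals):
                return ann
        return None

    site_by_key = {(s.chrom, s.pos): s for s in matrix.sites}
    rows = []
    for strain in matrix.strains:
        counts = dict.fromkeys(CATEGORIES, 0)
        for chrom, pos, alt in sorted(homozygous_variant_set(matrix, strain).mutations):
            ann = locate(chrom, pos)
            if ann is None or ann.transcript_id not in cds_sequences:
                continue
            effect = classify_coding_snv(ann, cds_sequences[ann.transcript_id], site_by_key[(chrom, pos)], alt)
            counts[effect.category] += 1
        rows.append({"strain": strain, **counts})
    return pd.DataFrame(rows)
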