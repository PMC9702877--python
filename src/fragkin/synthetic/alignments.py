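"""Synthetic aligned read pairs carrying known fragment lengths.

Each clean fragment becomes one properly-paired read pair whose signed
template-length (TLEN) fields are +L and -L, on a synthetic coordinate
space (no reference-genome realism, no sequence content). Contaminant
records exercise the standard extraction filters: PCR-duplicate pairs
sharing coordinates with a clean pair, supplementary alignments, and
pairs with mapping quality below 20. The sex-mismatch spike-in design
of the degradation experiments is emulated by labelling fragments with
chromosomes (male chrY fragments in female fluid).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from fragkin.errors import SpecificationError

__all__ = ["Contamination", "make_header", "emit_aligned_pairs", "write_sam", "write_fragment_tsv"]

_CONTIG_LEN = 60_000_000
_CONTIGS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
_READ_LEN = 100


@dataclass(frozen=True)
class Contamination:
    """Fractions of contaminant records to inject, relative to n fragments."""

    duplicates: float = 0.0
    supplementary: float = 0.0
    low_mapq: float = 0.0

    def __post_init__(self) -> None:
        for name in ("duplicates", "supplementary", "low_mapq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecificationError(f"{name} fraction must be in [0, 1]")


def make_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_references(list(_CONTIGS), [_CONTIG_LEN] * len(_CONTIGS))


def _make_pair(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    pos: int,
    length: int,
    mapq: int,
    duplicate: bool = False,
) -> list[pysam.AlignedSegment]:
    tid = header.references.index(chrom)
    mate_pos = pos + length - _READ_LEN
    pair = []
    for read1 in (True, False):
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.reference_id = tid
        seg.next_reference_id = tid
        seg.mapping_quality = mapq
        seg.cigarstring = f"{_READ_LEN}M"
        seg.is_paired = True
        seg.is_proper_pair = True
        seg.is_read1 = read1
        seg.is_read2 = not read1
        seg.is_duplicate = duplicate
        if read1:
            seg.reference_start = pos
            seg.next_reference_start = mate_pos
            seg.is_reverse = False
            seg.mate_is_reverse = True
            seg.template_length = length
        else:
            seg.reference_start = mate_pos
            seg.next_reference_start = pos
            seg.is_reverse = True
            seg.mate_is_reverse = False
            seg.template_length = -length
        pair.append(seg)
    return pair


def emit_aligned_pairs(
    lengths: Sequence[int] | np.ndarray,
    chrom_labels: Sequence[str],
    seed: int | np.random.Generator,
    contamination: Contamination = Contamination(),
) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    """Turn fragment lengths into aligned read-pair records.

    Each (length, chromosome) pair yields one clean proper pair with
    TLEN fields +L/-L and mapping quality >= 20. Contaminant records
    (coordinate-sharing duplicate pairs, supplementary alignments,
    low-MapQ pairs) are appended according to ``contamination``; a
    downstream extraction with the standard filters recovers exactly
    the clean input lengths.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) != len(chrom_labels):
        raise SpecificationError("lengths and chrom_labels must have the same size")
    unknown = set(chrom_labels) - set(_CONTIGS)
    if unknown:
        raise SpecificationError(f"unknown chromosome labels: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    header = make_header()
    records: list[pysam.AlignedSegment] = []
    n = len(lengths)

    clean_meta = []
    for i, (length, chrom) in enumerate(zip(lengths, chrom_labels)):
        pos = int(rng.integers(_READ_LEN, _CONTIG_LEN - int(length) - _READ_LEN))
        mapq = int(rng.integers(20, 61))
        clean_meta.append((chrom, pos, int(length), mapq))
        records.extend(_make_pair(header, f"frag{i:08d}", chrom, pos, int(length), mapq))

    n_dup = int(round(contamination.duplicates * n))
    for j in range(n_dup):
        chrom, pos, length, mapq = clean_meta[int(rng.integers(0, n))]
        records.extend(
            _make_pair(header, f"dup{j:08d}", chrom, pos, length, mapq, duplicate=True)
        )

    n_low = int(round(contamination.low_mapq * n))
    for j in range(n_low):
        chrom, pos, length, _ = clean_meta[int(rng.integers(0, n))]
        pos = int(rng.integers(_READ_LEN, _CONTIG_LEN - length - _READ_LEN))
        records.extend(
            _make_pair(header, f"lowq{j:08d}", chrom, pos, length, int(rng.integers(0, 20)))
        )

    n_sup = int(round(contamination.supplementary * n))
    for j in range(n_sup):
        chrom, pos, length, mapq = clean_meta[int(rng.integers(0, n))]
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"supp{j:08d}"
        seg.reference_id = header.references.index(chrom)
        seg.reference_start = int(rng.integers(_READ_LEN, _CONTIG_LEN // 2))
        seg.mapping_quality = mapq
        seg.cigarstring = f"{_READ_LEN}M"
        seg.is_paired = True
        seg.is_supplementary = True
        seg.template_length = length
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = seg.reference_start
        records.append(seg)

    return records, header


def write_sam(records, header: pysam.AlignmentHeader, path) -> None:
    """Write records as a (text) SAM file."""
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)


def write_fragment_tsv(lengths, chrom_labels, path) -> None:
    """Write fragments as a 2-column (chrom, length) TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in zip(chrom_labels, lengths):
            fh.write(f"{chrom}\t{int(length)}\n")
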