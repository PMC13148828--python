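"""HCLC generation from snATAC-seq fragment files.

A *high-coverage locus* is a maximal genomic interval covered by at least
``min_cov`` fragments within a single cell (default 3, i.e. "more than two
overlapping reads").  Per-cell loci are merged across cells into a
non-redundant locus set per chromosome, a binary locus-by-cell incidence
matrix is formed, and each cell's HCLC is its column sum.

Coordinates follow the 10x fragment-file dialect: 0-based half-open BED
intervals.  Overlap means at least one shared base; touching half-open
intervals do not overlap.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Human autosome names, with and without the UCSC "chr" prefix.  The prefix
#: style is auto-detected from the fragment file, so both spellings are
#: accepted by default.
AUTOSOMES: frozenset[str] = frozenset(
    [f"chr{i}" for i in range(1, 23)] + [str(i) for i in range(1, 23)]
)


class FragmentParseError(ValueError):
    """A malformed line in a fragment file (bad coordinates or field count)."""


class NoFragmentsError(ValueError):
    """No fragments survived filtering: nothing to compute HCLC from."""


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One mapped fragment: half-open interval tagged with a cell barcode.

    ``dup_count`` is carried through for provenance but ignored for
    coverage: duplicate counts reflect PCR amplification, not independent
    molecules, so each fragment row contributes coverage 1.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    dup_count: int = 1


@dataclass(frozen=True, slots=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class LocusCellMatrix:
    """Binary incidence of merged high-coverage loci (rows) by cells (columns)."""

    loci: list[GenomicInterval]
    barcodes: list[str]
    entries: np.ndarray  # bool, shape (n_loci, n_barcodes)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=bool)
        if self.entries.shape != (len(self.loci), len(self.barcodes)):
            raise ValueError("entries shape does not match loci/barcodes")


@dataclass
class HclcTable:
    """Per-barcode high-coverage locus counts.

    Every whitelisted barcode is present; barcodes without qualifying loci
    carry an HCLC of zero.
    """

    counts: pd.Series  # int, indexed by barcode

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts).astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("HCLC values must be non-negative")

    @property
    def n_barcodes(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.rename_axis("barcode").rename("hclc").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HclcTable":
        df = pd.read_csv(path, sep="\t")
        if not {"barcode", "hclc"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'barcode' and 'hclc'")
        return cls(pd.Series(df["hclc"].values, index=df["barcode"].values))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_barcodes(path: str | Path) -> set[str]:
    """Read a barcode whitelist, one barcode per line (plain or gzip)."""
    with _open_text(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _merge_plain(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge (start, end) pairs wherever they share >= 1 base."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_fragments(
    path: str | Path,
    whitelist: set[str],
    max_insert: int = 900,
    chroms: set[str] | None = None,
    exclude: Sequence[GenomicInterval] | None = None,
) -> Iterator[FragmentRecord]:
    """Stream filtered fragments from a 5-column fragment TSV.

    Keeps records whose barcode is whitelisted, whose chromosome is in
    ``chroms`` (default: human autosomes, either prefix style), whose insert
    size is strictly less than ``max_insert`` bp, and that do not overlap
    any exclusion interval.  Raises :class:`NoFragmentsError` if nothing
    survives.
    """
    if chroms is None:
        chroms = AUTOSOMES
    excl: dict[str, list[tuple[int, int]]] = defaultdict(list)
    if exclude:
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in exclude:
            by_chrom[iv.chrom].append((iv.start, iv.end))
        excl = {c: _merge_plain(ivs) for c, ivs in by_chrom.items()}

    def _excluded(chrom: str, start: int, end: int) -> bool:
        ivs = excl.get(chrom)
        if not ivs:
            return False
        i = bisect_right([s for s, _ in ivs], start)
        # candidate merged intervals: the one starting at/before `start`
        # and any starting inside [start, end)
        for s, e in ivs[max(0, i - 1):]:
            if s >= end:
                break
            if s < end and start < e:
                return True
        return False

    n_yielded = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FragmentParseError(
                    f"{path}, line {lineno}: expected >= 4 tab-separated fields"
                )
            chrom, start_s, end_s, barcode = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise FragmentParseError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from err
            if start >= end:
                raise FragmentParseError(
                    f"{path}, line {lineno}: start >= end ({start} >= {end})"
                )
            dup = 1
            if len(fields) >= 5:
                try:
                    dup = int(fields[4])
                except ValueError:
                    dup = 1
            if chrom not in chroms:
                continue
            if barcode not in whitelist:
                continue
            if end - start >= max_insert:
                continue
            if _excluded(chrom, start, end):
                continue
            n_yielded += 1
            yield FragmentRecord(chrom, start, end, barcode, dup)
    if n_yielded == 0:
        raise NoFragmentsError(f"{path}: no fragments retained after filtering")


def find_high_coverage_loci(
    cell_fragments: Sequence[GenomicInterval], min_cov: int = 3
) -> list[GenomicInterval]:
    """Maximal intervals where one cell's fragment coverage reaches ``min_cov``.

    Sweep-line over interval endpoints; at equal coordinates end events are
    processed before start events, consistent with half-open semantics.
    """
    if min_cov < 1:
        raise ValueError(f"min_cov must be >= 1, got {min_cov}")
    if not cell_fragments:
        return []
    chroms = {iv.chrom for iv in cell_fragments}
    if len(chroms) != 1:
        raise ValueError("find_high_coverage_loci expects intervals on one chromosome")
    chrom = chroms.pop()
    # event: (position, delta); sorting puts -1 (end) before +1 (start) at ties
    events = sorted(
        [(iv.start, +1) for iv in cell_fragments]
        + [(iv.end, -1) for iv in cell_fragments],
        key=lambda t: (t[0], t[1]),
    )
    loci: list[GenomicInterval] = []
    cov = 0
    open_start: int | None = None
    for pos, delta in events:
        new_cov = cov + delta
        if cov < min_cov <= new_cov:
            # coalesce with a run closed at this same position: the dip was
            # a transient between an end and a start event, not a real base
            if loci and loci[-1].end == pos:
                open_start = loci.pop().start
            else:
                open_start = pos
        elif new_cov < min_cov <= cov:
            assert open_start is not None
            loci.append(GenomicInterval(chrom, open_start, pos))
            open_start = None
        cov = new_cov
    return loci


def merge_loci(
    per_cell_loci: Iterable[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union-merge per-cell loci into a non-redundant set per chromosome.

    Two loci merge iff they share at least one base; touching half-open
    intervals stay separate.  Output is sorted and pairwise non-overlapping.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for loci in per_cell_loci:
        for iv in loci:
            by_chrom[iv.chrom].append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        for s, e in _merge_plain(by_chrom[chrom]):
            merged.append(GenomicInterval(chrom, s, e))
    return merged


def _check_sorted_disjoint(loci: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in loci:
        by_chrom[iv.chrom].append(iv)
    for chrom, ivs in by_chrom.items():
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end or b.start < a.start:
                raise ValueError(
                    f"locus list not sorted/non-overlapping on {chrom}: {a} vs {b}"
                )


def build_matrix_and_hclc(
    merged_loci: Sequence[GenomicInterval],
    fragments: Iterable[FragmentRecord],
    whitelist: set[str],
) -> tuple[LocusCellMatrix, HclcTable]:
    """Binary locus-by-cell incidence and per-cell HCLC (column sums).

    An entry is 1 iff the cell has at least one fragment sharing a base
    with the locus; multiple fragments on the same locus still count once.
    """
    _check_sorted_disjoint(merged_loci)
    barcodes = sorted(whitelist)
    bc_index = {b: j for j, b in enumerate(barcodes)}
    # per-chromosome sorted starts/ends for bisection
    chrom_loci: dict[str, tuple[list[int], list[int], list[int]]] = {}
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for i, iv in enumerate(merged_loci):
        by_chrom[iv.chrom].append((iv.start, iv.end, i))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        chrom_loci[chrom] = (
            [s for s, _, _ in ivs],
            [e for _, e, _ in ivs],
            [i for _, _, i in ivs],
        )
    entries = np.zeros((len(merged_loci), len(barcodes)), dtype=bool)
    for frag in fragments:
        j = bc_index.get(frag.barcode)
        if j is None:
            continue
        triple = chrom_loci.get(frag.chrom)
        if triple is None:
            continue
        starts, ends, idx = triple
        lo = bisect_right(ends, frag.start)  # first locus ending after frag.start
        hi = bisect_left(starts, frag.end)  # first locus starting at/after frag.end
        for k in range(lo, hi):
            entries[idx[k], j] = True
    hclc = pd.Series(entries.sum(axis=0).astype(np.int64), index=barcodes)
    return LocusCellMatrix(list(merged_loci), barcodes, entries), HclcTable(hclc)


def compute_hclc(
    fragments_path: str | Path,
    whitelist: set[str],
    max_insert: int = 900,
    min_cov: int = 3,
    chroms: set[str] | None = None,
    exclude: Sequence[GenomicInterval] | None = None,
) -> tuple[HclcTable, list[GenomicInterval]]:
    """Full preprocessing: fragment file -> per-cell HCLC.

    Stage 1 finds high-coverage loci per cell per chromosome; stage 2 merges
    them across cells and scores each cell against the merged set.  The
    fragment stream is buffered in memory grouped by (chromosome, barcode);
    the file does not need to be coordinate-sorted.
    """
    per_cell: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
    all_frags: list[FragmentRecord] = []
    for frag in read_fragments(
        fragments_path, whitelist, max_insert=max_insert, chroms=chroms, exclude=exclude
    ):
        per_cell[(frag.chrom, frag.barcode)].append(
            GenomicInterval(frag.chrom, frag.start, frag.end)
        )
        all_frags.append(frag)
    per_cell_loci = [
        find_high_coverage_loci(ivs, min_cov=min_cov) for ivs in per_cell.values()
    ]
    merged = merge_loci(per_cell_loci)
    logger.info(
        "HCLC preprocessing: %d fragments, %d cells with fragments, %d merged loci",
        len(all_frags),
        len({f.barcode for f in all_frags}),
        len(merged),
    )
    _, hclc = build_matrix_and_hclc(merged, all_frags, whitelist)
    return hclc, merged


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file into intervals (for exclusion regions)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FragmentParseError(
                    f"{path}, line {lineno}: expected >= 3 BED columns"
                )
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(loci: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
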