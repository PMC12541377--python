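"""Reading and writing of genomic interchange formats.

All coordinates are 0-based half-open (BED convention) internally; BAM
positions are converted on ingest by pysam. Fragments are whole sequenced
templates, one per read pair, never per read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

VALID_STRANDS = frozenset({"+", "-"})
VALID_ROLES = frozenset({"minus1_dyad", "plus1_dyad", "plus4_dyad", "ndr_center"})


class FormatError(ValueError):
    """A record that does not parse in its declared format."""


@dataclass(frozen=True, slots=True)
class Fragment:
    """One sequenced template as a genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    mapq: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("fragment chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # left of the two central bases for even lengths
        return (self.start + self.end - 1) // 2


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


def _read_bed3(path: Path) -> Iterator[Fragment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            yield Fragment(fields[0], start, end)


def _read_bedpe(path: Path) -> Iterator[Fragment]:
    # the fragment span is min(start1,start2)..max(end1,end2)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            if fields[0] != fields[3]:
                raise FormatError(
                    f"{path}:{lineno}: interchromosomal pair not supported"
                )
            try:
                s1, e1, s2, e2 = (int(fields[i]) for i in (1, 2, 4, 5))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            mapq = None
            if len(fields) >= 8:
                try:
                    mapq = int(fields[7])
                except ValueError:
                    mapq = None
            yield Fragment(fields[0], min(s1, s2), max(e1, e2), mapq)


def _read_bam(path: Path) -> Iterator[Fragment]:
    import pysam

    n_unpaired = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or not rec.is_paired
            ):
                if rec.is_paired is False and not rec.is_unmapped:
                    n_unpaired += 1
                continue
            # emit one fragment per template, from the leftmost mate
            if not rec.is_proper_pair or rec.template_length <= 0:
                continue
            yield Fragment(
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + rec.template_length,
                rec.mapping_quality,
            )
    if n_unpaired:
        warnings.warn(f"{path}: skipped {n_unpaired} unpaired reads", stacklevel=2)


def read_fragments(
    path: str | Path,
    format: str = "bed3",
    min_mapq: int = 0,
    dedup: bool = True,
) -> list[Fragment]:
    """Read fragments, drop low-quality templates, collapse exact duplicates.

    Parameters
    ----------
    path
        Input file in the declared format.
    format
        One of ``bam``, ``bedpe``, ``bed3``. For BAM, one fragment is
        emitted per properly paired template, built from the leftmost
        mate and its template length.
    min_mapq
        Fragments with a recorded mapping quality below this are dropped.
        BED input carries no mapping quality and is never dropped.
    dedup
        Collapse fragments with identical (chrom, start, end) to one,
        strand-agnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"bed3": _read_bed3, "bedpe": _read_bedpe, "bam": _read_bam}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    frags = readers[format](path)
    if min_mapq > 0:
        frags = (f for f in frags if f.mapq is None or f.mapq >= min_mapq)
    if dedup:
        return deduplicate(frags)
    return list(frags)


def deduplicate(frags: Iterable[Fragment]) -> list[Fragment]:
    """Collapse exact-duplicate (chrom, start, end) fragments to one."""
    seen: dict[tuple[str, int, int], Fragment] = {}
    for f in frags:
        seen.setdefault((f.chrom, f.start, f.end), f)
    return list(seen.values())


def size_filter(
    frags: Iterable[Fragment], min_len: int, max_len: int
) -> list[Fragment]:
    """Keep fragments with min_len <= length <= max_len (inclusive bounds)."""
    if not 0 <= min_len <= max_len:
        raise ValueError(f"invalid size window [{min_len}, {max_len}]")
    return [f for f in frags if min_len <= f.length <= max_len]


def read_anchors(path: str | Path) -> pd.DataFrame:
    """Read a feature-anchor table (TSV with header).

    Required columns: gene_id, chrom, pos, strand, role. Strand must be
    + or -; role one of minus1_dyad, plus1_dyad, plus4_dyad, ndr_center;
    (gene_id, role) unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = ["gene_id", "chrom", "pos", "strand", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        if row["strand"] not in VALID_STRANDS:
            raise FormatError(f"{path}: row {i + 2}: invalid strand {row['strand']!r}")
        if row["role"] not in VALID_ROLES:
            raise FormatError(f"{path}: row {i + 2}: invalid role {row['role']!r}")
        if row["pos"] < 0:
            raise FormatError(f"{path}: row {i + 2}: negative position")
    dup = df.duplicated(subset=["gene_id", "role"])
    if dup.any():
        genes = df.loc[dup, "gene_id"].unique().tolist()
        raise FormatError(f"{path}: duplicate (gene_id, role) for {genes}")
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_gene_set(path: str | Path) -> GeneSet:
    """Read a gene list: one id per line, optional '# name=<name>' header."""
    name = Path(path).stem
    members: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "name=" in line:
                    name = line.split("name=", 1)[1].strip()
                continue
            members.append(line)
    if len(members) != len(set(members)):
        raise FormatError(f"{path}: duplicate gene ids")
    return GeneSet(name, frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={gene_set.name}\n")
        for gid in sorted(gene_set.members):
            fh.write(gid + "\n")


def write_fragments_bed(frags: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as BED3 (sorted by chrom, start)."""
    rows = sorted(frags, key=lambda f: (f.chrom, f.start, f.end))
    with open(path, "w") as fh:
        for f in rows:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column chrom-sizes TSV into an ordered dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_bedgraph(track, path: str | Path) -> None:
    """Write a coverage track as 4-column bedGraph.

    Runs of equal value are merged; zero-valued runs are omitted (the
    bedGraph convention). Values must be finite.
    """
    with open(path, "w") as fh:
        for chrom in track.chroms():
            values = track[chrom]
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite values on {chrom}")
            if values.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int], norm: str = "cpm"):
    """Read a bedGraph file back into a CoverageTrack (zeros where absent)."""
    from .tracks import CoverageTrack

    data = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in data:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            data[chrom][start:end] = value
    return CoverageTrack(data, norm=norm, meta={"source": str(path)})
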