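"""Anchor-aligned metagene matrices, normalization and profile statistics.

A MetaMatrix is a features x relative-position matrix extracted around
per-gene anchor points (dyads or NDR centers). Rows are oriented so that
positive relative positions point downstream in the direction of
transcription; minus-strand rows are therefore reversed at extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import Fragment
from .tracks import CoverageTrack


@dataclass
class MetaMatrix:
    """Features x relative-position signal matrix, transcription-oriented."""

    gene_ids: list[str]
    values: np.ndarray  # shape (n_genes, 2*half_width + 1)
    half_width: int
    anchor_role: str = ""
    label: str = ""
    oriented: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != 2 * self.half_width + 1:
            raise ValueError("column count must equal 2*half_width + 1")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("row count must equal number of gene ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)

    def col_index(self, rel_pos: int) -> int:
        if abs(rel_pos) > self.half_width:
            raise ValueError(f"relative position {rel_pos} outside matrix")
        return rel_pos + self.half_width

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: Iterable[str]) -> "MetaMatrix":
        wanted = [g for g in gene_ids if g in set(self.gene_ids)]
        idx = [self.gene_ids.index(g) for g in wanted]
        return MetaMatrix(
            wanted, self.values[idx], self.half_width, self.anchor_role, self.label
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.positions)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        cols = df.columns.astype(int)
        half = int(cols.max())
        if not np.array_equal(cols, np.arange(-half, half + 1)):
            raise ValueError(f"{path}: columns are not contiguous -W..+W")
        return cls(list(df.index.astype(str)), df.to_numpy(), half)


def extract_matrix(
    track: CoverageTrack,
    anchors: pd.DataFrame,
    half_width: int,
    role: str | None = None,
) -> MetaMatrix:
    """Extract per-gene windows around anchors, transcription-oriented.

    Minus-strand rows are reversed so +x means downstream of the anchor
    in the direction of transcription. Anchors whose window would cross
    a chromosome boundary are dropped with a counted warning.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if role is not None:
        anchors = anchors[anchors["role"] == role]
    if anchors.empty:
        raise ValueError("no anchors to extract")
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for _, a in anchors.iterrows():
        chrom, pos, strand = a["chrom"], int(a["pos"]), a["strand"]
        if chrom not in track.data:
            n_dropped += 1
            continue
        vec = track.data[chrom]
        lo, hi = pos - half_width, pos + half_width + 1
        if lo < 0 or hi > vec.size:
            n_dropped += 1
            continue
        window = vec[lo:hi]
        if strand == "-":
            window = window[::-1]
        gene_ids.append(str(a["gene_id"]))
        rows.append(np.asarray(window, dtype=np.float64))
    if not rows:
        raise ValueError("all anchors fell outside chromosome bounds")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} out-of-bounds anchors", stacklevel=2)
    mat = MetaMatrix(
        gene_ids,
        np.vstack(rows),
        half_width,
        anchor_role=role or "",
        label=str(track.meta.get("label", "")),
    )
    return mat


def enrichment_over_mean(
    matrix: MetaMatrix, norm_halfwidth: int = 100, min_mean: float = 1e-3
) -> MetaMatrix:
    """Divide each row by its mean over the +/- norm_halfwidth window.

    This makes profiles from samples of very different depth directly
    comparable — the motivating case being nascent-chromatin libraries
    whose purification leaves a small fraction of the steady-state read
    depth. Rows whose window mean falls below ``min_mean`` are dropped
    (division by near-zero would amplify noise) and counted in a warning.
    """
    if norm_halfwidth > matrix.half_width:
        raise ValueError("normalization window exceeds matrix half-width")
    lo = matrix.col_index(-norm_halfwidth)
    hi = matrix.col_index(norm_halfwidth) + 1
    row_means = matrix.values[:, lo:hi].mean(axis=1)
    keep = row_means >= min_mean
    if not keep.any():
        raise ValueError("every row fell below the minimum window mean")
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} rows with window mean < {min_mean}", stacklevel=2
        )
    values = matrix.values[keep] / row_means[keep, None]
    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return MetaMatrix(
        gene_ids, values, matrix.half_width, matrix.anchor_role, matrix.label
    )


def column_mean(matrix: MetaMatrix) -> np.ndarray:
    """Positionwise mean profile over all rows."""
    if matrix.values.shape[0] < 1:
        raise ValueError("matrix has no rows")
    return matrix.values.mean(axis=0)


def zscore_profile(
    signal_profile: np.ndarray,
    input_profile: np.ndarray,
    window: slice | None = None,
) -> np.ndarray:
    """Input-subtracted, Z-scored positioning profile.

    ``d = signal - input`` is standardized to mean 0, sd 1 over the
    given window (the full profile by default): the standard rendering
    of a modified-nucleosome positioning profile against its total-MNase
    input.
    """
    signal_profile = np.asarray(signal_profile, dtype=np.float64)
    input_profile = np.asarray(input_profile, dtype=np.float64)
    if signal_profile.shape != input_profile.shape:
        raise ValueError("profiles must have equal length")
    d = signal_profile - input_profile
    win = d[window] if window is not None else d
    sd = win.std()
    if sd == 0:
        raise ValueError("zero variance: signal and input are offset copies")
    return (d - win.mean()) / sd


def window_statistic(
    matrix: MetaMatrix, center: int, width: int, stat: str = "mean"
) -> pd.Series:
    """Per-gene summary over a window of ``width`` bp centered at ``center``.

    Matches the boxplot statistics computed over, e.g., 20 bp around the
    +1 dyad or 200 bp around the NDR center.
    """
    if stat != "mean":
        raise ValueError(f"unsupported statistic {stat!r}")
    lo_rel = center - width // 2
    hi_rel = center + width // 2
    lo = matrix.col_index(lo_rel)
    hi = matrix.col_index(hi_rel) + 1
    vals = matrix.values[:, lo:hi].mean(axis=1)
    return pd.Series(vals, index=matrix.gene_ids, name=f"mean[{lo_rel},{hi_rel}]")


def extend_and_center(
    reads: Iterable[tuple[str, int, int, str]], ext: int = 150
) -> list[Fragment]:
    """Virtually extend single-end reads to ``ext`` bp fragments.

    Each read ``(chrom, start, end, strand)`` is replaced by an ``ext``
    bp fragment growing from its 5' end in read orientation; fragment
    centers then approximate dyads exactly as for paired-end data.
    """
    if ext < 1:
        raise ValueError("extension length must be >= 1")
    out: list[Fragment] = []
    for chrom, start, end, strand in reads:
        if strand == "+":
            out.append(Fragment(chrom, start, start + ext))
        elif strand == "-":
            out.append(Fragment(chrom, max(0, end - ext), end))
        else:
            raise ValueError(f"read without a valid strand: {strand!r}")
    return out
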