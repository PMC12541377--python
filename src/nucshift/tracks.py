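"""Per-bp dyad coverage tracks and their arithmetic.

A track holds one float vector per chromosome at 1 bp resolution. Raw
tracks count fragment centers; CPM normalization scales by one million
over the number of fragments contributing to non-excluded chromosomes
(the mitochondrial genome is conventionally excluded from the
denominator but its signal is retained and scaled by the same factor).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Fragment


class CoverageTrack:
    """1 bp-resolution signal vectors keyed by chromosome.

    Parameters
    ----------
    data
        Mapping chromosome -> float64 vector of per-bp signal.
    norm
        ``"raw"`` for fragment counts, ``"cpm"`` for counts per million,
        ``"diff"`` for differences of normalized tracks.
    n_fragments
        Number of fragments that produced a raw track (used as the CPM
        denominator after chromosome exclusion).
    """

    def __init__(
        self,
        data: Mapping[str, np.ndarray],
        norm: str = "raw",
        n_fragments: int | None = None,
        excluded_chroms: frozenset[str] | None = None,
        meta: dict | None = None,
    ):
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in data.items()}
        self.norm = norm
        self.n_fragments = n_fragments
        self.excluded_chroms = frozenset(excluded_chroms or ())
        self.meta = dict(meta or {})

    def chroms(self) -> list[str]:
        return list(self.data)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: v.size for c, v in self.data.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self, include_excluded: bool = True) -> float:
        return float(
            sum(
                v.sum()
                for c, v in self.data.items()
                if include_excluded or c not in self.excluded_chroms
            )
        )

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()},
            norm=self.norm,
            n_fragments=self.n_fragments,
            excluded_chroms=self.excluded_chroms,
            meta=dict(self.meta),
        )

    def _check_compatible(self, other: "CoverageTrack") -> None:
        if self.chrom_sizes() != other.chrom_sizes():
            raise ValueError("tracks have mismatched chromosomes or lengths")


def dyad_coverage(
    frags: Iterable[Fragment],
    chrom_sizes: Mapping[str, int],
    center_width: int = 3,
) -> CoverageTrack:
    """Pile up fragment centers into a raw 1 bp coverage track.

    Each fragment increments the ``center_width`` bp window centered on
    its midpoint (left-of-center base for even lengths) by one, clipped
    at chromosome edges. ``center_width`` must be odd so the window is
    symmetric around the midpoint.
    """
    if center_width < 1 or center_width % 2 == 0:
        raise ValueError("center_width must be a positive odd integer")
    half = center_width // 2
    mids: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    n = 0
    for f in frags:
        if f.chrom not in chrom_sizes:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        if f.end > chrom_sizes[f.chrom]:
            raise ValueError(
                f"fragment [{f.start},{f.end}) beyond end of {f.chrom} "
                f"({chrom_sizes[f.chrom]} bp)"
            )
        mids[f.chrom].append(f.midpoint)
        n += 1
    data = {}
    for chrom, size in chrom_sizes.items():
        vec = np.zeros(size, dtype=np.float64)
        if mids[chrom]:
            m = np.asarray(mids[chrom], dtype=np.int64)
            for off in range(-half, half + 1):
                pos = m + off
                ok = (pos >= 0) & (pos < size)
                np.add.at(vec, pos[ok], 1.0)
        data[chrom] = vec
    return CoverageTrack(
        data,
        norm="raw",
        n_fragments=n,
        meta={
            "center_width": center_width,
            "fragments_per_chrom": {c: len(v) for c, v in mids.items()},
        },
    )


def cpm_normalize(
    track: CoverageTrack, excluded: Iterable[str] = ("chrM",)
) -> CoverageTrack:
    """Scale a raw track to counts per million.

    The scale factor is 1e6 over the number of fragments whose centers
    fell on non-excluded chromosomes; excluded chromosomes are scaled by
    the same factor but never counted in the denominator.
    """
    if track.norm != "raw":
        raise ValueError(f"track is already normalized ({track.norm})")
    excluded = frozenset(excluded)
    denom = _fragments_on(track, excluded)
    if denom <= 0:
        raise ValueError("no fragments on non-excluded chromosomes")
    factor = 1e6 / denom
    out = track.copy()
    for c in out.data:
        out.data[c] *= factor
    out.norm = "cpm"
    out.excluded_chroms = excluded
    out.meta["cpm_denominator"] = denom
    return out


def _fragments_on(track: CoverageTrack, excluded: frozenset[str]) -> float:
    counts = track.meta.get("fragments_per_chrom")
    if counts is not None:
        return float(sum(v for c, v in counts.items() if c not in excluded))
    if track.n_fragments is None:
        raise ValueError("cannot determine fragment count for CPM denominator")
    # fall back to total count; accurate when excluded chroms carry none
    return float(track.n_fragments)


def mean_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Positionwise arithmetic mean of replicate tracks (all same norm)."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        first._check_compatible(t)
        if t.norm != first.norm:
            raise ValueError("tracks have mixed normalizations")
    out = first.copy()
    for t in tracks[1:]:
        for c in out.data:
            out.data[c] += t.data[c]
    for c in out.data:
        out.data[c] /= len(tracks)
    out.meta = {"source": "mean", "n_replicates": len(tracks)}
    return out


def diff_tracks(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Positionwise a - b; negative values preserved."""
    a._check_compatible(b)
    if a.norm != b.norm:
        raise ValueError("tracks have mixed normalizations")
    data = {c: a.data[c] - b.data[c] for c in a.data}
    return CoverageTrack(
        data, norm="diff", excluded_chroms=a.excluded_chroms, meta={"source": "diff"}
    )


def subtract_control(signal: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Background subtraction: signal - control, sign preserved.

    Used for ChEC tracks against a free-nuclease strain and for
    modification signal against its sequencing input. Both tracks must
    be normalized the same way.
    """
    return diff_tracks(signal, control)
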