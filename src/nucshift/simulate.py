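"""Synthetic chromatin fragment generator with known ground truth.

Emulates every signal class the pipeline consumes: steady-state and
nascent MNase fragments around promoter nucleosome-depleted regions
(NDRs), modified-nucleosome immunoprecipitation subpopulations offset
from the mean dyad, and ChEC cleavage fragments with a free-nuclease
background control. Every generator is deterministic given its seed
(counter-based Philox streams) and returns a truth table alongside the
fragments so that recovery can be checked against the planted values.

The default genome is two 200 kb chromosomes carrying 200 genes whose
-1 and +1 dyads sit 300 bp apart (the canonical average -1/+1 distance
of expressed genes), with gene-body nucleosomes every 165 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Fragment

#: nucleosome indices simulated per gene, transcription-oriented
NUC_INDICES = (-1, 1, 2, 3, 4)


@dataclass(frozen=True)
class ChromatinModel:
    """Layout and sampling law for a synthetic yeast-like genome."""

    n_genes: int = 200
    chrom_sizes: dict = field(
        default_factory=lambda: {"chrI": 200_000, "chrII": 200_000}
    )
    ndr_width: int = 300  # -1 to +1 dyad distance, bp
    spacing: int = 165  # nucleosome repeat length, bp
    frag_mean: float = 157.0  # fragment length law: Normal, truncated
    frag_sd: float = 12.0
    frag_min: int = 100
    frag_max: int = 220
    jitter_sd: float = 5.0  # positional sd of fragment centers around a dyad
    background_fraction: float = 0.1  # uniform genome-wide fragments
    nascent_thinning: float = 0.05  # survival fraction after purification
    modified_offset: int = 15  # bp, downstream offset of the modified pool
    modified_fraction: float = 1.0
    free_mnase_ndr_enrichment: float = 3.0  # background weight inside NDRs
    margin: int = 5_000  # gene-free zone at chromosome ends
    conditions: dict = field(default_factory=dict)  # label -> {gene: +1 shift, bp}

    def __post_init__(self) -> None:
        for frac in (self.background_fraction, self.nascent_thinning):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not self.frag_min <= self.frag_mean <= self.frag_max:
            raise ValueError("fragment length truncation excludes the mean")

    def with_condition(self, label: str, shifts: dict) -> "ChromatinModel":
        conds = dict(self.conditions)
        conds[label] = dict(shifts)
        return replace(self, conditions=conds)

    # ---- gene layout -------------------------------------------------

    def layout(self) -> pd.DataFrame:
        """Deterministic gene table: positions, strands, true dyads.

        Genes are spread evenly over the chromosomes, alternating
        strand. Dyad columns are genomic coordinates; +1 is downstream
        of the NDR center in the transcription direction.
        """
        chroms = list(self.chrom_sizes)
        per_chrom = int(np.ceil(self.n_genes / len(chroms)))
        rows = []
        g = 0
        for chrom in chroms:
            size = self.chrom_sizes[chrom]
            usable = size - 2 * self.margin
            step = usable // per_chrom
            for i in range(per_chrom):
                if g >= self.n_genes:
                    break
                center = self.margin + step // 2 + i * step
                strand = "+" if g % 2 == 0 else "-"
                sign = 1 if strand == "+" else -1
                half = self.ndr_width // 2
                plus1 = center + sign * half
                minus1 = center - sign * half
                plus4 = plus1 + sign * 3 * self.spacing
                rows.append(
                    {
                        "gene_id": f"gene{g:04d}",
                        "chrom": chrom,
                        "strand": strand,
                        "ndr_center": center,
                        "minus1_dyad": minus1,
                        "plus1_dyad": plus1,
                        "plus4_dyad": plus4,
                    }
                )
                g += 1
        return pd.DataFrame(rows)

    def anchors(self) -> pd.DataFrame:
        """The layout rendered as a feature-anchor table."""
        lay = self.layout()
        frames = []
        for role, col in [
            ("minus1_dyad", "minus1_dyad"),
            ("plus1_dyad", "plus1_dyad"),
            ("plus4_dyad", "plus4_dyad"),
            ("ndr_center", "ndr_center"),
        ]:
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": lay["gene_id"],
                        "chrom": lay["chrom"],
                        "pos": lay[col],
                        "strand": lay["strand"],
                        "role": role,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _truncated_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(np.int64)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _fragments_at(
    rng: np.random.Generator,
    model: ChromatinModel,
    chroms: np.ndarray,
    centers: np.ndarray,
    lengths: np.ndarray | None = None,
) -> list[Fragment]:
    """Build fragments whose coverage midpoint lands on the given centers."""
    n = centers.size
    if lengths is None:
        lengths = _truncated_lengths(
            rng, n, model.frag_mean, model.frag_sd, model.frag_min, model.frag_max
        )
    starts = centers - (lengths - 1) // 2
    ends = starts + lengths
    frags = []
    for chrom, s, e in zip(chroms, starts, ends):
        size = model.chrom_sizes[chrom]
        s = int(max(0, s))
        e = int(min(size, e))
        if e > s:
            frags.append(Fragment(str(chrom), s, e))
    return frags


def _dyad_positions(lay: pd.DataFrame, shifts: dict) -> pd.DataFrame:
    """Genomic dyad position per (gene, nucleosome index) with +1 shifts."""
    rows = []
    for _, g in lay.iterrows():
        sign = 1 if g["strand"] == "+" else -1
        shift = int(shifts.get(g["gene_id"], 0))
        for idx in NUC_INDICES:
            if idx == -1:
                pos = g["minus1_dyad"]
            else:
                pos = g["plus1_dyad"] + sign * (idx - 1) * lay_spacing(lay, g)
                if idx == 1:
                    pos = g["plus1_dyad"]
            if idx == 1:
                pos = pos + sign * shift
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "chrom": g["chrom"],
                    "strand": g["strand"],
                    "nuc": idx,
                    "dyad": int(pos),
                }
            )
    return pd.DataFrame(rows)


def lay_spacing(lay: pd.DataFrame, g: pd.Series) -> int:
    # spacing reconstructed from the +1/+4 distance (3 repeats)
    return int(round(abs(int(g["plus4_dyad"]) - int(g["plus1_dyad"])) / 3))


def simulate_mnase(
    model: ChromatinModel,
    condition: str = "reference",
    n_fragments: int = 50_000,
    seed: int = 0,
) -> tuple[list[Fragment], pd.DataFrame]:
    """Draw nucleosomal MNase fragments for one condition.

    Fragments are assigned uniformly over (gene, nucleosome) pairs;
    centers are Normal(dyad + planted shift, jitter sd); a
    ``background_fraction`` of fragments falls uniformly on the genome.
    Returns (fragments, truth table) where the truth table lists each
    gene's true (possibly shifted) dyads and its planted +1 shift.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    shifts = model.conditions.get(condition, {})
    rng = _rng(seed)
    lay = model.layout()
    dyads = _dyad_positions(lay, shifts)
    n_bg = int(rng.binomial(n_fragments, model.background_fraction))
    n_nuc = n_fragments - n_bg
    pick = rng.integers(0, len(dyads), size=n_nuc)
    centers = dyads["dyad"].to_numpy()[pick] + np.rint(
        rng.normal(0.0, model.jitter_sd, size=n_nuc)
    ).astype(np.int64)
    chroms = dyads["chrom"].to_numpy()[pick]
    frags = _fragments_at(rng, model, chroms, centers)
    # uniform background over concatenated chromosomes
    if n_bg:
        chrom_names = list(model.chrom_sizes)
        sizes = np.array([model.chrom_sizes[c] for c in chrom_names], dtype=float)
        bg_chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=sizes / sizes.sum())
        bg_centers = np.array(
            [rng.integers(0, sizes[i]) for i in bg_chrom_idx], dtype=np.int64
        )
        bg_chroms = np.array([chrom_names[i] for i in bg_chrom_idx])
        frags += _fragments_at(rng, model, bg_chroms, bg_centers)
    truth = lay.copy()
    truth["condition"] = condition
    truth["true_shift"] = truth["gene_id"].map(lambda g: int(shifts.get(g, 0)))
    sign = np.where(truth["strand"] == "+", 1, -1)
    truth["plus1_dyad_shifted"] = truth["plus1_dyad"] + sign * truth["true_shift"]
    return frags, truth


def simulate_nascent(
    model: ChromatinModel,
    base_condition: str = "reference",
    thinning: float | None = None,
    extra_jitter: float = 0.0,
    n_fragments: int = 50_000,
    seed: int = 0,
) -> tuple[list[Fragment], pd.DataFrame]:
    """Nascent-chromatin sample: the base condition, heavily thinned.

    Purification of newly replicated DNA retains only a small fraction
    of the library; each base fragment survives an independent
    Bernoulli(thinning) draw, optionally with extra positional jitter.
    """
    thinning = model.nascent_thinning if thinning is None else thinning
    if not 0.0 < thinning <= 1.0:
        raise ValueError("thinning must lie in (0, 1]")
    frags, truth = simulate_mnase(model, base_condition, n_fragments, seed)
    rng = _rng(seed + 1_000_003)
    keep = rng.random(len(frags)) < thinning
    kept = [f for f, k in zip(frags, keep) if k]
    if extra_jitter > 0:
        moved = []
        for f in kept:
            d = int(round(rng.normal(0.0, extra_jitter)))
            size = model.chrom_sizes[f.chrom]
            s = min(max(0, f.start + d), size - f.length)
            moved.append(Fragment(f.chrom, s, s + f.length))
        kept = moved
    truth = truth.copy()
    truth["condition"] = f"nascent:{base_condition}"
    return kept, truth


def simulate_modified_chip(
    model: ChromatinModel,
    offset: int | None = None,
    fraction: float | None = None,
    n_reads: int = 50_000,
    single_end: bool = False,
    read_length: int = 50,
    seed: int = 0,
):
    """Modified-nucleosome immunoprecipitation around the +1 dyad.

    A ``fraction`` of +1-derived fragments is re-centered at
    dyad + ``offset`` bp (transcription-oriented: downstream for
    positive offsets). With ``single_end=True`` the sample is emitted as
    5'-anchored single-end reads of ``read_length`` bp, to be run
    through the virtual-extension path. Returns (reads-or-fragments,
    truth table).
    """
    offset = model.modified_offset if offset is None else offset
    fraction = model.modified_fraction if fraction is None else fraction
    if abs(offset) >= model.spacing:
        raise ValueError("offset must be smaller than the nucleosome spacing")
    rng = _rng(seed)
    lay = model.layout()
    pick = rng.integers(0, len(lay), size=n_reads)
    sign = np.where(lay["strand"].to_numpy()[pick] == "+", 1, -1)
    dyad = lay["plus1_dyad"].to_numpy()[pick]
    modified = rng.random(n_reads) < fraction
    centers = dyad + np.where(modified, sign * offset, 0) + np.rint(
        rng.normal(0.0, model.jitter_sd, size=n_reads)
    ).astype(np.int64)
    chroms = lay["chrom"].to_numpy()[pick]
    frags = _fragments_at(rng, model, chroms, centers)
    truth = lay.copy()
    truth["modified_offset"] = offset
    truth["modified_fraction"] = fraction
    if not single_end:
        return frags, truth
    reads = []
    read_strand = rng.random(len(frags)) < 0.5
    for f, plus in zip(frags, read_strand):
        if plus:
            reads.append((f.chrom, f.start, min(f.start + read_length, f.end), "+"))
        else:
            reads.append((f.chrom, max(f.end - read_length, f.start), f.end, "-"))
    return reads, truth


def simulate_chec(
    model: ChromatinModel,
    protein_profile: str = "ndr_center_peak",
    n_fragments: int = 50_000,
    with_free_mnase_control: bool = True,
    peak_fraction: float = 0.6,
    peak_sd: float = 10.0,
    seed: int = 0,
):
    """ChEC cleavage fragments plus a free-nuclease background control.

    The protein sample mixes planted cleavage peaks (at NDR centers for
    ``ndr_center_peak``, at the flanking -1/+1 dyads for
    ``flanking_peaks``) with the same background law as the control.
    The control is background only: uniform genome-wide cleavage with
    an ``free_mnase_ndr_enrichment``-fold weight inside NDRs, matching
    the nucleosome-free accessibility of promoters to untethered
    nuclease. Fragment lengths are uniform on [20, 200] bp, exercising
    the 0-200 bp ChEC size class. Returns (protein_frags, control_frags,
    truth) — control is None when not requested.
    """
    if protein_profile not in ("ndr_center_peak", "flanking_peaks"):
        raise ValueError(f"unknown protein profile {protein_profile!r}")
    rng = _rng(seed)
    lay = model.layout()

    def background(n: int, stream: np.random.Generator) -> list[Fragment]:
        # mixture: NDR-enriched vs uniform, weight set by the enrichment factor
        w_ndr = model.free_mnase_ndr_enrichment
        ndr_bp = model.n_genes * model.ndr_width
        total_bp = sum(model.chrom_sizes.values())
        p_ndr = w_ndr * ndr_bp / (w_ndr * ndr_bp + (total_bp - ndr_bp))
        in_ndr = stream.random(n) < p_ndr
        n_in = int(in_ndr.sum())
        pick = stream.integers(0, len(lay), size=n_in)
        offs = stream.integers(
            -model.ndr_width // 2, model.ndr_width // 2 + 1, size=n_in
        )
        centers_in = lay["ndr_center"].to_numpy()[pick] + offs
        chroms_in = lay["chrom"].to_numpy()[pick]
        n_out = n - n_in
        chrom_names = list(model.chrom_sizes)
        sizes = np.array([model.chrom_sizes[c] for c in chrom_names], dtype=float)
        idx = stream.choice(len(chrom_names), size=n_out, p=sizes / sizes.sum())
        centers_out = np.array(
            [stream.integers(0, sizes[i]) for i in idx], dtype=np.int64
        )
        chroms_out = np.array([chrom_names[i] for i in idx])
        chroms = np.concatenate([chroms_in, chroms_out])
        centers = np.concatenate([centers_in, centers_out])
        lengths = stream.integers(20, 201, size=n)
        return _fragments_at(rng, model, chroms, centers, lengths)

    n_peak = int(rng.binomial(n_fragments, peak_fraction))
    if protein_profile == "ndr_center_peak":
        sites = lay["ndr_center"].to_numpy()
        site_chroms = lay["chrom"].to_numpy()
    else:
        sites = np.concatenate(
            [lay["minus1_dyad"].to_numpy(), lay["plus1_dyad"].to_numpy()]
        )
        site_chroms = np.concatenate([lay["chrom"].to_numpy()] * 2)
    pick = rng.integers(0, sites.size, size=n_peak)
    centers = sites[pick] + np.rint(rng.normal(0.0, peak_sd, size=n_peak)).astype(
        np.int64
    )
    lengths = rng.integers(20, 201, size=n_peak)
    protein = _fragments_at(rng, model, site_chroms[pick], centers, lengths)
    protein += background(n_fragments - n_peak, rng)
    control = background(n_fragments, rng) if with_free_mnase_control else None
    truth = lay.copy()
    truth["protein_profile"] = protein_profile
    return protein, control, truth


def synthetic_gene_lists(
    universe_size: int = 4701,
    annotated_size: int = 136,
    cluster_size: int = 228,
    overlap: int = 31,
):
    """Synthetic stand-in gene lists with prescribed overlap structure.

    Builds a universe of ``universe_size`` synthetic gene ids, an
    annotation set (e.g. ribosomal-protein genes) of ``annotated_size``,
    and a cluster of ``cluster_size`` sharing exactly ``overlap``
    members with the annotation. A deterministic surrogate for gene
    lists that live outside the repository: only the set sizes and the
    overlap carry information, which is exactly what the hypergeometric
    enrichment consumes.

    Returns (cluster, annotated, universe) GeneSets.
    """
    from .io import GeneSet

    if overlap > min(annotated_size, cluster_size):
        raise ValueError("overlap exceeds a set size")
    if annotated_size + cluster_size - overlap > universe_size:
        raise ValueError("sets do not fit in the universe")
    ids = [f"gene{i:05d}" for i in range(universe_size)]
    annotated = ids[:annotated_size]
    cluster = ids[:overlap] + ids[annotated_size : annotated_size + cluster_size - overlap]
    return (
        GeneSet("cluster", frozenset(cluster)),
        GeneSet("annotated", frozenset(annotated)),
        GeneSet("universe", frozenset(ids)),
    )
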