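"""Per-gene nucleosome peak calling, shift quantification and classification.

The central readout: for every gene, the dyad-coverage peak nearest the
annotated -1/+1/+4 dyad is located on a Gaussian-smoothed metagene row,
and its displacement between a condition and a reference quantifies how
far the nucleosome has moved. Negative displacements are upstream (left)
shifts in the direction of transcription.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneSet
from .metagene import MetaMatrix

QC_OK = "ok"
QC_LOW_COVERAGE = "low_coverage"
QC_NO_PEAK = "no_peak"


def gaussian_smooth(row: np.ndarray, sd: float) -> np.ndarray:
    """Smooth with a Gaussian kernel truncated at 3 sd, renormalized at edges."""
    if sd < 0:
        raise ValueError("smoothing sd must be non-negative")
    if sd == 0:
        return np.asarray(row, dtype=np.float64).copy()
    half = int(np.ceil(3 * sd))
    x = np.arange(-half, half + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (x / sd) ** 2)
    kernel /= kernel.sum()
    num = np.convolve(row, kernel, mode="same")
    # renormalize by kernel mass actually inside the row at each position
    den = np.convolve(np.ones_like(row, dtype=np.float64), kernel, mode="same")
    return num / den


def _argmax_toward_zero(smoothed: np.ndarray, rel: np.ndarray) -> int:
    """Index of the max; ties broken toward rel 0, then upstream (negative)."""
    m = smoothed.max()
    tied = np.flatnonzero(smoothed == m)
    order = sorted(tied, key=lambda i: (abs(rel[i]), rel[i]))
    return order[0]


def call_peak(
    matrix: MetaMatrix,
    search_halfwidth: int = 100,
    smooth_sd: float = 10.0,
    min_height: float | None = None,
) -> pd.DataFrame:
    """Call one peak per gene in a window around the annotated dyad.

    Each row is smoothed with a Gaussian kernel (sd ``smooth_sd`` bp,
    truncated at 3 sd, edge-renormalized) and the peak is the argmax of
    the smoothed row within +/- ``search_halfwidth`` bp, ties broken
    toward the annotated dyad and then upstream.

    Quality flags: ``low_coverage`` when the raw row mean is below
    ``min_height`` (default: 25% of the median row mean), ``no_peak``
    when the smoothed search window is flat.

    Returns a DataFrame with columns gene_id, rel_pos, height, qc.
    """
    if search_halfwidth > matrix.half_width:
        raise ValueError("search window exceeds matrix half-width")
    raw_means = matrix.values.mean(axis=1)
    if min_height is None:
        min_height = 0.25 * float(np.median(raw_means))
    lo = matrix.col_index(-search_halfwidth)
    hi = matrix.col_index(search_halfwidth) + 1
    rel = np.arange(-search_halfwidth, search_halfwidth + 1)
    records = []
    for i, gene_id in enumerate(matrix.gene_ids):
        smoothed = gaussian_smooth(matrix.values[i], smooth_sd)[lo:hi]
        if np.allclose(smoothed, smoothed[0]):
            records.append((gene_id, 0, 0.0, QC_NO_PEAK))
            continue
        j = _argmax_toward_zero(smoothed, rel)
        qc = QC_LOW_COVERAGE if raw_means[i] < min_height else QC_OK
        records.append((gene_id, int(rel[j]), float(smoothed[j]), qc))
    return pd.DataFrame(records, columns=["gene_id", "rel_pos", "height", "qc"])


def shift_table(cond: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Signed per-gene peak displacement of a condition vs a reference.

    delta = rel_pos(condition) - rel_pos(reference); negative means the
    peak moved upstream (left) in the direction of transcription. Genes
    missing an ``ok`` call in either table are excluded and counted.
    """
    cond_ok = cond[cond["qc"] == QC_OK].set_index("gene_id")
    ref_ok = ref[ref["qc"] == QC_OK].set_index("gene_id")
    shared = cond_ok.index.intersection(ref_ok.index)
    n_all = len(cond["gene_id"].unique())
    if shared.empty:
        raise ValueError("no genes with valid peak calls in both tables")
    n_excluded = n_all - len(shared)
    if n_excluded > 0:
        warnings.warn(f"excluded {n_excluded} genes without paired calls", stacklevel=2)
    delta = (cond_ok.loc[shared, "rel_pos"] - ref_ok.loc[shared, "rel_pos"]).astype(int)
    return pd.DataFrame({"gene_id": shared, "delta": delta.to_numpy()})


def summarize_shifts(
    records: pd.DataFrame, groups: Sequence[GeneSet]
) -> pd.DataFrame:
    """Per-group mean shift and normal-approximation 95% CI.

    Groups with fewer than 2 member records are dropped with a warning.
    """
    by_gene = records.set_index("gene_id")["delta"]
    rows = []
    for gs in groups:
        deltas = by_gene[by_gene.index.isin(gs.members)].to_numpy(dtype=float)
        if deltas.size < 2:
            warnings.warn(f"group {gs.name!r} has <2 records; dropped", stacklevel=2)
            continue
        mean = deltas.mean()
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        rows.append((gs.name, deltas.size, mean, mean - 1.96 * se, mean + 1.96 * se))
    return pd.DataFrame(
        rows, columns=["group", "n", "mean_delta", "ci_low", "ci_high"]
    )


def classify_maturation_shift(
    nascent: pd.DataFrame, steady: pd.DataFrame, threshold: float = 30.0
) -> pd.DataFrame:
    """Split genes into shifted / nonshifted by the maturation displacement.

    The maturation delta is rel_pos(nascent) - rel_pos(steady): a
    positive delta means the nascent peak sits downstream of its mature
    position, i.e. the nucleosome moves right-to-left while chromatin
    matures. Genes with delta strictly greater than ``threshold`` bp are
    labelled ``shifted``; everything else ``nonshifted``.
    """
    table = shift_table(nascent, steady)
    table["cluster"] = np.where(table["delta"] > threshold, "shifted", "nonshifted")
    return table[["gene_id", "delta", "cluster"]]


def kmeans_targets(
    diff_matrix: MetaMatrix, k: int = 2, seed: int = 0, n_init: int = 10
) -> dict[str, GeneSet]:
    """Define target/nontarget genes by k-means on difference-signal rows.

    Rows of a condition-difference metagene matrix are clustered with
    Lloyd's algorithm (Euclidean, ``n_init`` restarts, best inertia).
    The cluster with the larger mean absolute difference is labelled
    ``target``; with k > 2 the remaining clusters are ``nontarget``,
    ``nontarget2``, ... in decreasing order of mean absolute difference.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    X = diff_matrix.values
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    if np.allclose(X, X[0]):
        raise ValueError("identical rows: no cluster structure")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    magnitude = [
        np.abs(X[labels == c]).mean() if (labels == c).any() else -np.inf
        for c in range(k)
    ]
    order = np.argsort(magnitude)[::-1]
    names = ["target"] + [
        "nontarget" if i == 1 else f"nontarget{i}" for i in range(1, k)
    ]
    out: dict[str, GeneSet] = {}
    for name, c in zip(names, order):
        members = [g for g, l in zip(diff_matrix.gene_ids, labels) if l == c]
        if members:
            out[name] = GeneSet(name, frozenset(members))
    return out
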