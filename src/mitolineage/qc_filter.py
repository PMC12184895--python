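"""Sequencing-error and frequency filters for mitochondrial VAF matrices.

Mitochondrial sites are covered far more deeply than nuclear ones, so raw
per-base sequencing errors produce spurious low-VAF calls.  Under a random
error rate *e*, a specific alternate base arises with probability e/3 per
read, and the chance of seeing at least m identical alternate reads among
n by error alone is the binomial survival probability

    p(m) = 1                                   if m = 0
    p(m) = 1 - sum_{i<m} Binom(i | n, e/3)     if m >= 1.

A call is kept only when its alternate-read count reaches the smallest k
with p(k) <= FPR, i.e. when sequencing error alone is an implausible
explanation at the chosen false-positive rate.  Defaults e = 1e-3,
FPR = 5e-7.

A second filter removes variants whose positive-cell fraction is extreme:
variants positive in almost no cells or in the large majority of cells
(germline-like) cannot separate lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .io_matrix import VafDataset, from_counts


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing error rate and acceptable false-positive rate."""

    e: float = 1e-3
    fpr: float = 5e-7

    def __post_init__(self) -> None:
        if not 0 < self.e < 1:
            raise ValueError(f"error rate e must be in (0,1), got {self.e}")
        if not 0 < self.fpr < 1:
            raise ValueError(f"fpr must be in (0,1), got {self.fpr}")


@dataclass(frozen=True)
class FrequencyFilter:
    """Bounds on the fraction of positive cells and minimum coverage.

    A variant positive in more than ``max_cell_fraction`` of covered cells
    is treated as germline-like: germline mitochondrial variants sit at
    high VAF in the large majority of a donor's cells, while clone markers
    in a multi-clone sample are confined to a minority of cells.  A
    variant positive in fewer than ``min_cell_fraction`` of cells (default
    5%, a clone-scale minimum) is cell-private noise rather than a clone
    marker.
    """

    min_cell_fraction: float = 0.05
    max_cell_fraction: float = 0.70
    min_cells_covered: int = 5

    def __post_init__(self) -> None:
        if not self.min_cell_fraction < self.max_cell_fraction:
            raise ValueError("min_cell_fraction must be < max_cell_fraction")


def error_prob(m: int, n: int, model: ErrorModel = ErrorModel()) -> float:
    """Probability of >= m identical alternate reads among n by error alone.

    p(0) = 1 exactly; p is non-increasing in m at fixed n.
    """
    if m < 0 or n < 0:
        raise ValueError("m and n must be non-negative")
    if m > n:
        raise ValueError(f"m={m} exceeds depth n={n}")
    if m == 0:
        return 1.0
    return float(binom.sf(m - 1, n, model.e / 3.0))


def min_alt_reads(n: int, model: ErrorModel = ErrorModel()) -> int:
    """Smallest alternate-read count k with error_prob(k, n) <= FPR.

    Returns n + 1 when no attainable count passes at this depth (in
    particular k = 1 for n = 0): the site cannot yield a confident call.
    """
    if n < 0:
        raise ValueError("depth must be non-negative")
    if n == 0:
        return 1
    # sf is monotone in m, so bisect on m in [1, n]
    p = model.e / 3.0
    lo, hi = 1, n
    if binom.sf(hi - 1, n, p) > model.fpr:
        return n + 1
    while lo < hi:
        mid = (lo + hi) // 2
        if binom.sf(mid - 1, n, p) <= model.fpr:
            hi = mid
        else:
            lo = mid + 1
    return lo


def _min_alt_reads_vector(depths: np.ndarray, model: ErrorModel) -> np.ndarray:
    """min_alt_reads evaluated once per distinct depth value."""
    uniq = np.unique(depths)
    table = {int(n): min_alt_reads(int(n), model) for n in uniq}
    return np.vectorize(table.__getitem__)(depths)


def apply_error_filter(ds: VafDataset, model: ErrorModel = ErrorModel()) -> VafDataset:
    """Zero out calls explainable by sequencing error; drop empty variants.

    An entry is zeroed (alt = 0, VAF = 0) when its alternate-read count is
    below the depth-dependent threshold k; depth is unchanged, so missing
    entries stay missing.  Variants left with no positive cell are removed.
    """
    if ds.n_mutations == 0:
        return ds.copy()
    k = _min_alt_reads_vector(ds.depth, model)
    alt = np.where(ds.alt < k, 0, ds.alt)
    keep = (alt > 0).any(axis=1)
    if keep.sum() == 0:
        warnings.warn("error filter removed every mutation", stacklevel=2)
    out = from_counts(
        [m for m, k_ in zip(ds.mutations, keep) if k_],
        ds.cells,
        alt[keep],
        ds.depth[keep],
        dict(ds.cell_annotations) if ds.cell_annotations else None,
    )
    return out


def positive_fraction(ds: VafDataset, positive_vaf_threshold: float = 0.01) -> np.ndarray:
    """Per-mutation fraction of covered cells with VAF above threshold."""
    covered = ds.depth > 0
    pos = (np.nan_to_num(ds.vaf) > positive_vaf_threshold) & covered
    n_cov = covered.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_cov > 0, pos.sum(axis=1) / np.maximum(n_cov, 1), 0.0)
    return frac


def apply_frequency_filter(
    ds: VafDataset,
    filt: FrequencyFilter = FrequencyFilter(),
    positive_vaf_threshold: float = 0.01,
    by_annotation_group: bool = False,
) -> VafDataset:
    """Remove variants with extreme positive-cell fractions or sparse coverage.

    A variant is kept when its positive-cell fraction (among covered
    cells) lies within [min_cell_fraction, max_cell_fraction] and it is
    covered in at least ``min_cells_covered`` cells.  With
    ``by_annotation_group`` and annotations present, the fraction rule
    must additionally hold within at least one annotation group
    (sample-level frequency).
    """
    if ds.n_mutations == 0:
        return ds.copy()
    frac = positive_fraction(ds, positive_vaf_threshold)
    n_cov = (ds.depth > 0).sum(axis=1)
    keep = (
        (frac >= filt.min_cell_fraction)
        & (frac <= filt.max_cell_fraction)
        & (n_cov >= filt.min_cells_covered)
    )
    if by_annotation_group and ds.cell_annotations:
        labels = np.array([ds.cell_annotations.get(c, "") for c in ds.cells])
        ok_any = np.zeros(ds.n_mutations, dtype=bool)
        for g in np.unique(labels):
            cols = labels == g
            covered = ds.depth[:, cols] > 0
            pos = (np.nan_to_num(ds.vaf[:, cols]) > positive_vaf_threshold) & covered
            nc = covered.sum(axis=1)
            f = np.where(nc > 0, pos.sum(axis=1) / np.maximum(nc, 1), 0.0)
            ok_any |= (f >= filt.min_cell_fraction) & (f <= filt.max_cell_fraction)
        keep &= ok_any
    if keep.sum() == 0:
        warnings.warn("frequency filter removed every mutation", stacklevel=2)
    return ds.subset_mutations(keep)


def drop_low_coverage_cells(ds: VafDataset, min_total_reads: int) -> VafDataset:
    """Optional cell-level gate: drop cells with too few total MT reads.

    Upstream variant calling typically enforces this already (order 1,000
    reads for scRNA-seq, 2,000 for scATAC-seq), so it is off by default in
    the pipeline.
    """
    totals = ds.depth.sum(axis=0)
    keep = totals >= min_total_reads
    idx = np.flatnonzero(keep)
    ann = None
    if ds.cell_annotations:
        ann = {c: ds.cell_annotations[c] for i in idx for c in [ds.cells[i]] if c in ds.cell_annotations}
    return from_counts(
        list(ds.mutations),
        [ds.cells[i] for i in idx],
        ds.alt[:, idx],
        ds.depth[:, idx],
        ann,
    )
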