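"""Benchmarking utilities: VAF-cutoff baseline, ARI, sibling-triplet ROC/PR.

The VAF-cutoff baseline mimics the common practice of calling a variant
informative when any cell reaches a heteroplasmy threshold (0.2, the GTEx
convention), excluding variants positive in every cell.

The sibling-triplet evaluation probes fine-scale lineage accuracy: for
every set of three samples containing exactly one true sibling pair
(clones sharing a parental clone, i.e. the same MRCA), a method should
rank the sibling pair as the closest of the three pairwise distances.
Triplets split into two difficulty regimes by where the odd sample comes
from: within_clone (it descends from the same MRCA — genetically close,
hard) and between_clones (different MRCA — easier).  Pooling pairwise
distances (negated, so nearer means a higher sibling score) across
triplets against sibling labels yields ROC and PR curves per scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn import metrics as _skm

from .io_matrix import MutationId, VafDataset

WITHIN_CLONE = "within_clone"
BETWEEN_CLONES = "between_clones"


@dataclass
class TripletRecord:
    samples: tuple[str, str, str]
    sibling_pair: tuple[str, str]
    scenario: str
    pair_distances: tuple[float, float, float] | None = None
    pair_labels: tuple[int, int, int] | None = None


@dataclass
class CurveSummary:
    roc_points: np.ndarray  # (fpr, tpr)
    pr_points: np.ndarray  # (recall, precision)
    auc_roc: float
    auc_pr: float
    top1_accuracy: float | None = None


def vaf_cutoff_baseline(ds: VafDataset, threshold: float = 0.2) -> list[MutationId]:
    """Variants reaching VAF >= threshold in at least one (but not every) cell."""
    vaf = np.nan_to_num(ds.vaf)
    covered = ds.depth > 0
    hit = (vaf >= threshold) & covered
    any_hit = hit.any(axis=1)
    n_cov = covered.sum(axis=1)
    universal = hit.sum(axis=1) == np.maximum(n_cov, 1)
    keep = any_hit & ~universal
    return [m for m, k in zip(ds.mutations, keep) if k]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError(f"partition lengths differ: {len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) < 2:
        raise ValueError("need at least 2 elements")
    return float(_skm.adjusted_rand_score(labels_a, labels_b))


def _ancestors_or_self(clone: str, mrca_of: dict[str, str | None]) -> set[str]:
    out = set()
    node: str | None = clone
    while node is not None:
        out.add(node)
        node = mrca_of.get(node)
    return out


def enumerate_triplets(
    clones: dict[str, str], mrca: dict[str, str | None]
) -> list[TripletRecord]:
    """All 3-sample sets with exactly one true sibling pair, by scenario.

    ``clones`` maps sample -> clone, ``mrca`` maps clone -> parental clone
    (None at the root).  Two samples are a sibling pair when their clones
    differ but share the same (non-None) parent.  Sets with zero or
    multiple sibling pairs (e.g. three mutual siblings) are excluded.
    The scenario is within_clone when the odd sample's lineage passes
    through the pair's MRCA, else between_clones.
    """

    def is_sibling(s1: str, s2: str) -> bool:
        c1, c2 = clones[s1], clones[s2]
        return c1 != c2 and mrca.get(c1) is not None and mrca.get(c1) == mrca.get(c2)

    records = []
    for trio in combinations(sorted(clones), 3):
        pairs = list(combinations(trio, 2))
        sib = [p for p in pairs if is_sibling(*p)]
        if len(sib) != 1:
            continue
        pair = sib[0]
        odd = next(s for s in trio if s not in pair)
        pair_mrca = mrca[clones[pair[0]]]
        scenario = (
            WITHIN_CLONE
            if pair_mrca in _ancestors_or_self(clones[odd], mrca)
            else BETWEEN_CLONES
        )
        records.append(TripletRecord(samples=trio, sibling_pair=pair, scenario=scenario))
    return records


def score_triplets(
    triplets: list[TripletRecord], dm_labels: list[str], d: np.ndarray
) -> list[TripletRecord]:
    """Fill pair distances and sibling labels from a distance matrix."""
    idx = {s: i for i, s in enumerate(dm_labels)}
    out = []
    for t in triplets:
        pairs = list(combinations(t.samples, 2))
        dists = tuple(float(d[idx[a], idx[b]]) for a, b in pairs)
        labels = tuple(1 if set(p) == set(t.sibling_pair) else 0 for p in pairs)
        out.append(
            TripletRecord(t.samples, t.sibling_pair, t.scenario, dists, labels)
        )
    return out


def triplet_auc(triplets: list[TripletRecord]) -> dict[str, CurveSummary]:
    """ROC/PR per scenario, pooling pairs with score = negated distance.

    AUROC uses the rank (Mann-Whitney) convention with tied scores
    averaged; AUPR is the step-interpolated average precision.  Also
    reports per-triplet top-1 accuracy (sibling pair strictly nearest).
    """
    out: dict[str, CurveSummary] = {}
    for scenario in (WITHIN_CLONE, BETWEEN_CLONES):
        subset = [t for t in triplets if t.scenario == scenario]
        if not subset:
            warnings.warn(f"no triplets for scenario {scenario}", stacklevel=2)
            continue
        scores, labels = [], []
        top1 = 0
        for t in subset:
            if t.pair_distances is None or t.pair_labels is None:
                raise ValueError("triplets must be scored first (score_triplets)")
            scores.extend(-dd for dd in t.pair_distances)
            labels.extend(t.pair_labels)
            sib_d = t.pair_distances[t.pair_labels.index(1)]
            others = [dd for dd, l in zip(t.pair_distances, t.pair_labels) if l == 0]
            top1 += int(all(sib_d < o for o in others))
        scores = np.asarray(scores)
        labels = np.asarray(labels)
        fpr, tpr, _ = _skm.roc_curve(labels, scores)
        prec, rec, _ = _skm.precision_recall_curve(labels, scores)
        out[scenario] = CurveSummary(
            roc_points=np.column_stack([fpr, tpr]),
            pr_points=np.column_stack([rec[::-1], prec[::-1]]),
            auc_roc=float(_skm.roc_auc_score(labels, scores)),
            auc_pr=float(_skm.average_precision_score(labels, scores)),
            top1_accuracy=top1 / len(subset),
        )
    return out
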