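"""Dirichlet-process Gaussian mixture selection of informative MT mutations.

A lineage-informative mitochondrial mutation is heteroplasmic in some
clones and absent in others, so its VAF distribution across cells is
multimodal.  For each mutation the cross-cell VAF vector y is rescaled to
mean 0 / sd 1 and modelled as a DP mixture of Gaussians,

    y_i ~ N(y_i | mu_i, sigma_i^2),   (mu_i, sigma_i^2) ~ G,   G ~ DP(alpha, G0),

with a conjugate Normal-Inverse-Gamma base measure G0 (mu0 = 0, kappa0 = 1,
a0 = 2, b0 = 1 — uninformative on standardized data).  Inference is a
collapsed Gibbs sampler: component parameters are integrated out and each
cell's component assignment is resampled in turn from its posterior given
all other assignments, with the Student-t posterior-predictive density.

The posterior is summarized by the modal number of occupied components
across post-burn-in sweeps (ignoring components holding less than
``min_component_weight`` of cells), taking the component assignment of the
last sweep attaining that mode.  Components are ordered by decreasing
mixing proportion and a mutation is called informative when it has at
least two components whose top-two means, back-transformed to the VAF
scale, differ by more than the cutoff (default 0.05, the scale of a
typical minor allele frequency).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_matrix import MutationId, VafDataset

logger = logging.getLogger(__name__)

# NIG base-measure hyperparameters on standardized data
_MU0, _KAPPA0, _A0, _B0 = 0.0, 1.0, 2.0, 1.0


@dataclass(frozen=True)
class DpgmmConfig:
    """Sampler and selection settings.

    ``n_iter`` counts full Gibbs sweeps; when None it defaults to 10,000
    for fewer than 100 cells and 5,000 otherwise, with burn-in at half the
    chain.  ``informative_cutoff`` is on the VAF scale.
    """

    alpha: float = 0.1
    n_iter: int | None = None
    n_burnin: int | None = None
    seed: int = 0
    min_component_weight: float = 0.02
    informative_cutoff: float = 0.05
    min_cells: int = 10
    standardized_scale_diff: bool = False

    def resolve_iters(self, n_cells: int) -> tuple[int, int]:
        n_iter = self.n_iter if self.n_iter is not None else (10_000 if n_cells < 100 else 5_000)
        n_burnin = self.n_burnin if self.n_burnin is not None else n_iter // 2
        if not n_burnin < n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        return n_iter, n_burnin


@dataclass
class DpgmmFit:
    """Posterior summary of one mutation's VAF mixture.

    Means and variances are on the original VAF scale; components are
    ordered by decreasing weight.  ``top2_mean_diff`` is NaN when fewer
    than two components were found.
    """

    mutation: MutationId | None
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    top2_mean_diff: float
    standardization: tuple[float, float]
    n_cells_used: int

    @property
    def informative(self) -> bool:
        return self.n_components >= 2 and not math.isnan(self.top2_mean_diff)


def standardize(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Rescale to mean 0 / sd 1, returning (z, center, scale).

    Missing (NaN) entries are excluded.  A zero-spread vector cannot be
    standardized and raises; callers short-circuit such mutations to a
    single component.
    """
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    center = float(y.mean())
    scale = float(y.std(ddof=0))
    if scale <= 1e-12 * max(1.0, abs(center)):
        raise ValueError("zero standard deviation: no standardization possible")
    return (y - center) / scale, center, scale


@njit(cache=True)
def _gibbs_chain(z, n_iter, n_burnin, alpha, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = z.shape[0]
    kappa0, a0, b0 = 1.0, 2.0, 1.0
    kmax = n + 1
    counts = np.zeros(kmax, np.int64)
    sums = np.zeros(kmax)
    sumsqs = np.zeros(kmax)
    assign = np.zeros(n, np.int64)
    counts[0] = n
    s0 = 0.0
    q0 = 0.0
    for j in range(n):
        s0 += z[j]
        q0 += z[j] * z[j]
    sums[0] = s0
    sumsqs[0] = q0
    n_active = 1

    # per-size constants: a_m = a0 + m/2
    lgr = np.empty(n + 1)
    for m in range(n + 1):
        am = a0 + 0.5 * m
        lgr[m] = math.lgamma(am + 0.5) - math.lgamma(am)

    keep = n_iter - n_burnin
    saved = np.empty((keep, n), np.int16)
    w = np.empty(kmax)
    lalpha = math.log(alpha)

    for it in range(n_iter):
        for i in range(n):
            y = z[i]
            c = assign[i]
            counts[c] -= 1
            sums[c] -= y
            sumsqs[c] -= y * y
            if counts[c] == 0:
                n_active -= 1
                last = n_active
                if c != last:
                    counts[c] = counts[last]
                    sums[c] = sums[last]
                    sumsqs[c] = sumsqs[last]
                    for j in range(n):
                        if assign[j] == last:
                            assign[j] = c
                counts[last] = 0
                sums[last] = 0.0
                sumsqs[last] = 0.0

            best = -1.0e300
            for c2 in range(n_active + 1):
                if c2 < n_active:
                    m = counts[c2]
                    s1 = sums[c2]
                    s2 = sumsqs[c2]
                    lw = math.log(m)
                else:
                    m = 0
                    s1 = 0.0
                    s2 = 0.0
                    lw = lalpha
                km = kappa0 + m
                am = a0 + 0.5 * m
                mum = s1 / km  # mu0 = 0
                if m > 0:
                    ybar = s1 / m
                    bm = b0 + 0.5 * (s2 - s1 * ybar) + kappa0 * m * ybar * ybar / (2.0 * km)
                else:
                    bm = b0
                nu = 2.0 * am
                sc2 = bm * (km + 1.0) / (am * km)
                t = y - mum
                lw += lgr[m] - 0.5 * math.log(nu * math.pi * sc2) - (am + 0.5) * math.log1p(
                    t * t / (nu * sc2)
                )
                w[c2] = lw
                if lw > best:
                    best = lw

            tot = 0.0
            for c2 in range(n_active + 1):
                w[c2] = math.exp(w[c2] - best)
                tot += w[c2]
            u = np.random.random() * tot
            acc = 0.0
            cnew = n_active
            for c2 in range(n_active + 1):
                acc += w[c2]
                if u <= acc:
                    cnew = c2
                    break
            if cnew == n_active:
                n_active += 1
            assign[i] = cnew
            counts[cnew] += 1
            sums[cnew] += y
            sumsqs[cnew] += y * y

        if it >= n_burnin:
            for j in range(n):
                saved[it - n_burnin, j] = assign[j]
    return saved


def _single_component_fit(
    y: np.ndarray, mutation: MutationId | None, n_used: int
) -> DpgmmFit:
    mean = float(np.nanmean(y)) if n_used else float("nan")
    var = float(np.nanvar(y)) if n_used else float("nan")
    return DpgmmFit(
        mutation=mutation,
        n_components=1,
        weights=np.array([1.0]),
        means=np.array([mean]),
        variances=np.array([var]),
        top2_mean_diff=float("nan"),
        standardization=(mean, 0.0),
        n_cells_used=n_used,
    )


def _summarize_sweep(
    labels: np.ndarray, z: np.ndarray, min_count: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Component weights/means/variances from one sweep's assignment.

    Means and variances are NIG posterior means given the members, which
    stay finite even for tiny components.  Components below ``min_count``
    members are dropped and weights renormalized.
    """
    sizes = np.bincount(labels)
    keep = np.flatnonzero(sizes >= max(min_count, 1))
    if keep.size == 0:  # all components are dust; fall back to the largest
        keep = np.array([int(np.argmax(sizes))])
    weights, means, variances = [], [], []
    for c in keep:
        members = z[labels == c]
        m = members.size
        s1 = members.sum()
        km = _KAPPA0 + m
        am = _A0 + 0.5 * m
        ybar = s1 / m
        bm = _B0 + 0.5 * ((members - ybar) ** 2).sum() + _KAPPA0 * m * ybar**2 / (2 * km)
        weights.append(m)
        means.append(s1 / km)
        variances.append(bm / (am - 1.0))
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    means = np.asarray(means)
    variances = np.asarray(variances)
    # order by decreasing weight; ties broken by ascending mean
    order = np.lexsort((means, -weights))
    return weights[order], means[order], variances[order]


def fit_dpgmm(
    y: np.ndarray,
    cfg: DpgmmConfig = DpgmmConfig(),
    mutation: MutationId | None = None,
    seed: int | None = None,
) -> DpgmmFit:
    """Fit the DP Gaussian mixture to one mutation's cross-cell VAFs.

    ``y`` may contain NaN (uncovered cells), which are excluded.  The fit
    is deterministic for a given seed (default ``cfg.seed``).
    """
    y = np.asarray(y, dtype=float)
    obs = y[~np.isnan(y)]
    n = obs.size
    if n < 2:
        raise ValueError(f"need at least 2 non-missing VAFs, got {n}")
    try:
        z, center, scale = standardize(obs)
    except ValueError:
        return _single_component_fit(obs, mutation, n)

    n_iter, n_burnin = cfg.resolve_iters(n)
    chain_seed = int((cfg.seed if seed is None else seed) % (2**31))
    saved = _gibbs_chain(z, n_iter, n_burnin, cfg.alpha, chain_seed)

    min_count = int(math.ceil(cfg.min_component_weight * n))
    n_comp_per_sweep = np.array(
        [(np.bincount(row) >= max(min_count, 1)).sum() for row in saved]
    )
    n_comp_per_sweep = np.maximum(n_comp_per_sweep, 1)
    counts = np.bincount(n_comp_per_sweep)
    modal_k = int(np.argmax(counts))  # argmax takes the smallest on ties
    last_idx = int(np.flatnonzero(n_comp_per_sweep == modal_k)[-1])
    weights, means_z, vars_z = _summarize_sweep(saved[last_idx], z, min_count)

    means = means_z * scale + center
    variances = vars_z * scale**2
    k = weights.size
    if k >= 2:
        diff_scale = means_z if cfg.standardized_scale_diff else means
        top2 = float(abs(diff_scale[0] - diff_scale[1]))
    else:
        top2 = float("nan")
    return DpgmmFit(
        mutation=mutation,
        n_components=k,
        weights=weights,
        means=means,
        variances=variances,
        top2_mean_diff=top2,
        standardization=(center, scale),
        n_cells_used=n,
    )


def select_informative(
    ds: VafDataset, cfg: DpgmmConfig = DpgmmConfig()
) -> tuple[list[MutationId], list[DpgmmFit]]:
    """Fit every mutation and return the informative ones.

    A mutation is selected when its fit has at least two components and
    the top-two component means (largest mixing proportions) differ by
    more than ``cfg.informative_cutoff``.  Mutations with fewer than
    ``cfg.min_cells`` covered cells are skipped.  Per-mutation chain seeds
    are derived deterministically from ``cfg.seed`` and the mutation's
    position in the dataset.
    """
    selected: list[MutationId] = []
    fits: list[DpgmmFit] = []
    for i, mut in enumerate(ds.mutations):
        y = ds.vaf[i]
        n_obs = int((~np.isnan(y)).sum())
        if n_obs < cfg.min_cells:
            logger.info("skipping %s: only %d covered cells (< %d)", mut, n_obs, cfg.min_cells)
            continue
        seed_i = (cfg.seed * 1_000_003 + 7_919 * i + 1) % (2**31)
        fit = fit_dpgmm(y, cfg, mutation=mut, seed=seed_i)
        fits.append(fit)
        if fit.n_components >= 2 and fit.top2_mean_diff > cfg.informative_cutoff:
            selected.append(mut)
    if not selected:
        warnings.warn("no informative mutations selected", stacklevel=2)
    return selected, fits


def fits_to_frame(fits: list[DpgmmFit]):
    """Flatten fits into a tidy table (one row per mutation)."""
    import pandas as pd

    rows = []
    for f in fits:
        rows.append(
            {
                "mutation": str(f.mutation) if f.mutation else "",
                "n_components": f.n_components,
                "weights": ";".join(f"{w:.4f}" for w in f.weights),
                "means": ";".join(f"{m:.4f}" for m in f.means),
                "variances": ";".join(f"{v:.6f}" for v in f.variances),
                "top2_mean_diff": f.top2_mean_diff,
                "n_cells_used": f.n_cells_used,
            }
        )
    return pd.DataFrame(rows)
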