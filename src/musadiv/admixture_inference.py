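"""Bayesian admixture inference and Evanno ΔK model selection.

The model is the admixture model with correlated allele frequencies: each
individual draws every allele copy from one of K populations according to
its membership vector q (Dirichlet(alpha) prior), and each population's
allele frequencies at a locus are drawn around shared ancestral
frequencies PA with population-specific divergence F_k (the F-model:
``P_kl ~ Dir(PA_l (1 - F_k) / F_k)``, small F_k meaning tight correlation
with the ancestral pool). Inference is by Gibbs sampling with Metropolis
steps for alpha, F and PA (see :mod:`musadiv._gibbs`).

Model size selection follows the ΔK heuristic: LnP(K) is estimated per
run as ``mean(lnL) - var(lnL)/2`` over recorded sweeps, and
``ΔK = |L''(K)| / sd_over_runs(L(K))`` peaks at the strongest hierarchical
level of structure. Population labels are unidentifiable across runs, so
membership matrices are aligned by greedy column matching before any
comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from musadiv import _gibbs
from musadiv.structure_encoding import MISSING_SLOT, EncodedMatrix

log = logging.getLogger("musadiv")


@dataclass(frozen=True)
class AdmixturePriors:
    """Hyperparameters of the sampler's prior and proposal distributions.

    ``f_prior_a / f_prior_b`` give a Beta prior on each F_k with mean 0.01
    and standard deviation 0.05, matching the published defaults of the
    correlated-frequency model; ``alpha`` has a uniform prior on
    (0, alpha_max) explored by a log-scale random walk of step 0.1.
    """

    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_step: float = 0.1
    f_init: float = 0.01
    f_prior_a: float = 0.0296
    f_prior_b: float = 2.9304
    f_step: float = 0.2
    pa_step: float = 0.1


@dataclass
class RunResult:
    """One chain's output: posterior-mean membership and LnP(K)."""

    k: int
    run: int
    seed: int
    q_hat: np.ndarray
    lnl_trace: np.ndarray  # full trace, burn-in included
    lnpk: float
    alpha: float
    f: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.q_hat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q_hat rows must sum to 1")


def encode_alleles(matrix: EncodedMatrix) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Map slot allele sizes to dense per-locus indices.

    Returns ``(X, J, sizes)``: X has shape (n, L, 3) with -1 for missing,
    J the allele count per locus, and ``sizes`` the size corresponding to
    each index.
    """
    n, L, _ = matrix.slots.shape
    X = np.full((n, L, 3), -1, dtype=np.int64)
    J = np.zeros(L, dtype=np.int64)
    sizes: list[np.ndarray] = []
    for l in range(L):
        col = matrix.slots[:, l, :]
        observed = np.unique(col[col != MISSING_SLOT])
        sizes.append(observed)
        J[l] = max(len(observed), 1)
        lookup = {int(a): j for j, a in enumerate(observed)}
        for i in range(n):
            for s in range(3):
                v = int(col[i, s])
                if v != MISSING_SLOT:
                    X[i, l, s] = lookup[v]
    return X, J, sizes


def gibbs_admixture(
    matrix: EncodedMatrix,
    k: int,
    burnin: int,
    iters: int,
    seed: int,
    priors: AdmixturePriors = AdmixturePriors(),
) -> RunResult:
    """Run one Gibbs chain on a triploid-coded matrix.

    Identical seed and input give bitwise-identical output. For K = 1 the
    membership matrix is exactly 1 and LnP(K) is still estimated from the
    composite log-likelihood trace.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if matrix.slots.size == 0:
        raise ValueError("empty encoded matrix")
    X, J, _ = encode_alleles(matrix)
    q_hat, lnl, alpha, f = _gibbs.run_chain(
        X, J, k, burnin, iters, seed,
        priors.alpha_init, priors.alpha_max, priors.alpha_step,
        priors.f_init, priors.f_prior_a, priors.f_prior_b, priors.f_step,
        priors.pa_step,
    )
    return RunResult(
        k=k, run=0, seed=seed, q_hat=q_hat, lnl_trace=lnl,
        lnpk=lnpk_estimate(lnl[burnin:]), alpha=alpha, f=f,
    )


def run_sweep(
    matrix: EncodedMatrix,
    ks: range | list[int],
    runs_per_k: int,
    burnin: int,
    iters: int,
    base_seed: int,
    priors: AdmixturePriors = AdmixturePriors(),
) -> list[RunResult]:
    """Replicate chains over a K grid; per-run seed = base + 1000 K + run."""
    results = []
    for k in ks:
        for run in range(runs_per_k):
            res = gibbs_admixture(matrix, k, burnin, iters, base_seed + 1000 * k + run, priors)
            res.run = run
            results.append(res)
        log.info("admixture K=%d: %d runs done", k, runs_per_k)
    return results


def lnpk_estimate(lnl_samples) -> float:
    """Model-evidence approximation ``mean(lnL) - var(lnL) / 2``."""
    x = np.asarray(lnl_samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 log-likelihood samples")
    return float(x.mean() - x.var(ddof=1) / 2.0)


def evanno_delta_k(lnp_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """ΔK table from per-K replicate LnP values.

    L'(K) = mean L(K) - mean L(K-1); |L''(K)| = |L'(K+1) - L'(K)|;
    ΔK = |L''(K)| / sd(L(K)) with the sample (n-1) standard deviation.
    ΔK is undefined (NaN) at the grid ends and wherever sd = 0.
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(lnp_by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lpp = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            delta = lpp / sd[k] if sd[k] > 0 else np.nan
        else:
            lpp = delta = np.nan
        rows.append({"K": k, "mean_l": mean[k], "sd_l": sd[k],
                     "l_prime": lp, "l_second_abs": lpp, "delta_k": delta})
    return pd.DataFrame(rows).set_index("K")


def select_k(table: pd.DataFrame) -> int:
    """K with maximal ΔK; ties break toward the smallest K."""
    defined = table["delta_k"].dropna()
    if defined.empty:
        raise ValueError("no defined ΔK values")
    best = defined.max()
    return int(min(k for k, v in defined.items() if v == best))


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """corr[i, j] = Pearson(a[:, i], b[:, j]); NaN for constant columns."""
    k1, k2 = a.shape[1], b.shape[1]
    out = np.full((k1, k2), np.nan)
    for i in range(k1):
        for j in range(k2):
            if np.ptp(a[:, i]) > 0 and np.ptp(b[:, j]) > 0:
                out[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    return out


def align_labels(runs: list[np.ndarray], reference: int = 0) -> list[np.ndarray]:
    """Permute each run's columns to best match the reference run.

    Greedy matching on column-wise Pearson correlation (ties toward the
    lowest index pair); undefined correlations rank last. Population labels
    carry no meaning across chains, so this resolves label switching
    before averaging or comparing membership matrices.
    """
    ref = np.asarray(runs[reference], dtype=float)
    K = ref.shape[1]
    aligned = []
    for idx, run in enumerate(runs):
        q = np.asarray(run, dtype=float)
        if q.shape != ref.shape:
            raise ValueError("all runs must share the reference's shape")
        if idx == reference or K == 1:
            aligned.append(q.copy())
            continue
        corr = _pearson_columns(ref, q)
        score = np.where(np.isnan(corr), -np.inf, corr)
        perm = np.empty(K, dtype=int)
        used_ref, used_run = set(), set()
        for _ in range(K):
            best, pair = -np.inf, None
            for i, j in itertools.product(range(K), range(K)):
                if i in used_ref or j in used_run:
                    continue
                if pair is None or score[i, j] > best:
                    best, pair = score[i, j], (i, j)
            i, j = pair
            perm[i] = j
            used_ref.add(i)
            used_run.add(j)
        aligned.append(q[:, perm])
    return aligned


#: Membership bins as printed interval labels (upper edges inclusive).
MEMBERSHIP_BIN_EDGES = (0.60, 0.80, 0.90, 1.0)
ADMIXTURE_THRESHOLD = 0.90  # q* <= 0.90 flags an admixed accession


def classify_membership(q_hat: np.ndarray) -> pd.DataFrame:
    """Bin each accession by its maximum membership q*.

    Bins 1-4 cover (0.24-0.60], (0.60-0.80], (0.80-0.90] and (0.90-1];
    an accession is admixed iff q* <= 0.90 (strict boundary: q* = 0.90 is
    still admixed).
    """
    q = np.asarray(q_hat, dtype=float)
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("membership rows must sum to 1")
    q_star = q.max(axis=1)
    if (q_star < 1.0 / q.shape[1] - 1e-9).any():
        raise ValueError("row maximum below 1/K is impossible")
    bins = 1 + np.searchsorted(MEMBERSHIP_BIN_EDGES[:-1], q_star, side="left")
    return pd.DataFrame(
        {
            "q_star": q_star,
            "bin": bins,
            "admixed": q_star <= ADMIXTURE_THRESHOLD,
            "population": q.argmax(axis=1),
        }
    )


def lnp_by_k(results: list[RunResult]) -> dict[int, list[float]]:
    """Group per-run LnP(K) estimates by K (run order preserved)."""
    out: dict[int, list[float]] = {}
    for res in results:
        out.setdefault(res.k, []).append(res.lnpk)
    return out


def best_run(results: list[RunResult], k: int) -> RunResult:
    """The highest-LnP run at a given K."""
    runs = [r for r in results if r.k == k]
    if not runs:
        raise ValueError(f"no runs at K={k}")
    return max(runs, key=lambda r: r.lnpk)
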