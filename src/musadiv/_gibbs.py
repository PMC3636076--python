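"""Compiled Gibbs sweep for the admixture model with correlated frequencies.

State per sweep, updated in order:

1. ``Z`` — origin population of every observed allele copy, multinomial
   with mass proportional to ``q_ik * p_klj``;
2. ``P`` — population allele frequencies, Dirichlet posterior under the
   F-model prior ``Dir(PA_l * (1 - F_k) / F_k)`` plus assignment counts;
3. ``Q`` — individual memberships, ``Dir(alpha + copy counts)``;
4. ``alpha`` — log-scale random-walk Metropolis, uniform prior on
   (0, alpha_max);
5. ``F_k`` — log-scale random-walk Metropolis with a Beta prior;
6. ``PA`` — ancestral frequencies, pairwise mass-transfer Metropolis with
   a flat Dirichlet(1, ..., 1) prior.

Missing slots (negative allele index) are skipped in every count, which
marginalizes them by omission. The composite log-likelihood
``sum log sum_k q_ik p_klj`` over observed copies is recorded each sweep
with the state at the top of the sweep.
"""

import math

import numpy as np
from numba import njit

_TINY = 1e-12


@njit(cache=True)
def _sample_dirichlet(params, nj, out):
    s = 0.0
    for j in range(nj):
        a = params[j]
        if a < 1e-9:
            a = 1e-9
        g = np.random.gamma(a, 1.0)
        if g < _TINY:
            g = _TINY
        out[j] = g
        s += g
    for j in range(nj):
        out[j] /= s


@njit(cache=True)
def _log_dirichlet_pdf(x, params, nj):
    s = 0.0
    tot = 0.0
    for j in range(nj):
        a = params[j]
        if a < 1e-9:
            a = 1e-9
        s += (a - 1.0) * math.log(x[j]) - math.lgamma(a)
        tot += a
    return s + math.lgamma(tot)


@njit(cache=True)
def run_chain(X, J, K, burnin, iters, seed,
              alpha_init, alpha_max, alpha_step,
              f_init, f_prior_a, f_prior_b, f_step,
              pa_step):
    """Run one chain; returns (Q_hat, lnl trace, alpha, F)."""
    np.random.seed(seed)
    n, L, S = X.shape
    Jmax = 0
    for l in range(L):
        if J[l] > Jmax:
            Jmax = J[l]
    Q = np.full((n, K), 1.0 / K)
    PA = np.zeros((L, Jmax))
    P = np.zeros((K, L, Jmax))
    for l in range(L):
        for j in range(J[l]):
            PA[l, j] = 1.0 / J[l]
            for k in range(K):
                P[k, l, j] = 1.0 / J[l]
    F = np.full(K, f_init)
    alpha = alpha_init
    probs = np.zeros(K)
    cnt = np.zeros((K, L, Jmax))
    rmat = np.zeros((n, K))
    tmp = np.zeros(Jmax)
    qsum = np.zeros((n, K))
    lnl = np.zeros(burnin + iters)

    for sweep in range(burnin + iters):
        # Z: origin of each observed copy, plus counts and log-likelihood
        cnt[:, :, :] = 0.0
        rmat[:, :] = 0.0
        ll = 0.0
        for i in range(n):
            for l in range(L):
                for s in range(S):
                    j = X[i, l, s]
                    if j < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        v = Q[i, k] * P[k, l, j]
                        probs[k] = v
                        tot += v
                    ll += math.log(tot)
                    u = np.random.random() * tot
                    acc = 0.0
                    z = K - 1
                    for k in range(K):
                        acc += probs[k]
                        if u <= acc:
                            z = k
                            break
                    cnt[z, l, j] += 1.0
                    rmat[i, z] += 1.0
        lnl[sweep] = ll

        # P | Z under the correlated-frequency (F-model) prior
        for k in range(K):
            lam = (1.0 - F[k]) / F[k]
            for l in range(L):
                for j in range(J[l]):
                    tmp[j] = PA[l, j] * lam + cnt[k, l, j]
                _sample_dirichlet(tmp, J[l], P[k, l])

        if K > 1:
            # Q | Z
            for i in range(n):
                for k in range(K):
                    probs[k] = alpha + rmat[i, k]
                _sample_dirichlet(probs, K, Q[i])

            # alpha: log-scale random walk, Uniform(0, alpha_max) prior
            slq = 0.0
            for i in range(n):
                for k in range(K):
                    slq += math.log(Q[i, k])
            prop = alpha * math.exp(alpha_step * np.random.normal())
            if 0.0 < prop < alpha_max:
                cur = n * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) + (alpha - 1.0) * slq
                new = n * (math.lgamma(K * prop) - K * math.lgamma(prop)) + (prop - 1.0) * slq
                if math.log(np.random.random()) < new - cur + math.log(prop / alpha):
                    alpha = prop

        # F_k: log-scale random walk, Beta(f_prior_a, f_prior_b) prior
        for k in range(K):
            fcur = F[k]
            fprop = fcur * math.exp(f_step * np.random.normal())
            if not 0.0 < fprop < 1.0:
                continue
            lam_p = (1.0 - fprop) / fprop
            lam_c = (1.0 - fcur) / fcur
            delta = 0.0
            for l in range(L):
                for j in range(J[l]):
                    tmp[j] = PA[l, j] * lam_p
                delta += _log_dirichlet_pdf(P[k, l], tmp, J[l])
                for j in range(J[l]):
                    tmp[j] = PA[l, j] * lam_c
                delta -= _log_dirichlet_pdf(P[k, l], tmp, J[l])
            delta += (f_prior_a - 1.0) * math.log(fprop / fcur)
            delta += (f_prior_b - 1.0) * math.log((1.0 - fprop) / (1.0 - fcur))
            delta += math.log(fprop / fcur)  # Jacobian of the log-scale walk
            if math.log(np.random.random()) < delta:
                F[k] = fprop

        # PA per locus: transfer mass between two alleles (flat prior)
        for l in range(L):
            if J[l] < 2:
                continue
            j1 = np.random.randint(J[l])
            j2 = np.random.randint(J[l])
            if j1 == j2:
                continue
            d = (np.random.random() - 0.5) * pa_step
            a1 = PA[l, j1] + d
            a2 = PA[l, j2] - d
            if a1 <= 1e-6 or a2 <= 1e-6:
                continue
            delta = 0.0
            for k in range(K):
                lam = (1.0 - F[k]) / F[k]
                delta += (
                    math.lgamma(max(PA[l, j1] * lam, 1e-9))
                    + math.lgamma(max(PA[l, j2] * lam, 1e-9))
                    - math.lgamma(max(a1 * lam, 1e-9))
                    - math.lgamma(max(a2 * lam, 1e-9))
                    + (a1 - PA[l, j1]) * lam * math.log(P[k, l, j1])
                    + (a2 - PA[l, j2]) * lam * math.log(P[k, l, j2])
                )
            if math.log(np.random.random()) < delta:
                PA[l, j1] = a1
                PA[l, j2] = a2

        if sweep >= burnin:
            # population labels can swap mid-chain when structure is weak;
            # align each recorded sample to the running mean (greedy column
            # matching on dot-product similarity) before accumulating
            if sweep == burnin or K == 1:
                for i in range(n):
                    for k in range(K):
                        qsum[i, k] += Q[i, k]
            else:
                sim = np.zeros((K, K))
                for k in range(K):
                    for j in range(K):
                        s_ = 0.0
                        for i in range(n):
                            s_ += qsum[i, k] * Q[i, j]
                        sim[k, j] = s_
                perm = np.full(K, -1)
                used = np.zeros(K, np.int64)
                for _ in range(K):
                    best = -1.0
                    bk = -1
                    bj = -1
                    for k in range(K):
                        if perm[k] >= 0:
                            continue
                        for j in range(K):
                            if used[j] == 1:
                                continue
                            if sim[k, j] > best:
                                best = sim[k, j]
                                bk = k
                                bj = j
                    perm[bk] = bj
                    used[bj] = 1
                for i in range(n):
                    for k in range(K):
                        qsum[i, k] += Q[i, perm[k]]

    return qsum / iters, lnl, alpha, F
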