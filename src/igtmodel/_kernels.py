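"""Numba-compiled numerical core: trial loops, agents and the MCMC chain.

Everything here speaks plain arrays; the public modules wrap these kernels
with validated, labelled types. Deck indices are 0-based here, parameter
vectors are always length 8 in the canonical order
``(A, alpha, c, lam, eps_p, eps_n, k, w)``; PVL models ignore the last four.

Model codes: 0 = PVL-Delta, 1 = PVL-DecayRI, 2 = VPP.
Transform codes: 0 = U * Phi(raw) (probit-normal), 1 = identity.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PVL_DELTA = 0
PVL_DECAY = 1
VPP = 2

_SQRT2 = 1.4142135623730951


@njit(cache=True)
def norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@njit(cache=True)
def to_native8(raw, kinds, ubounds, out8):
    """Map raw-scale parameters to the canonical native length-8 vector."""
    for j in range(8):
        out8[j] = 0.0
    out8[7] = 1.0  # w: PVL models behave as pure RL
    # a model's raw parameter order coincides with the canonical order
    for p in range(kinds.shape[0]):
        if kinds[p] == 0:
            out8[p] = ubounds[p] * norm_cdf(raw[p])
        else:
            out8[p] = raw[p]


@njit(cache=True)
def loglik_trials(model, params8, choices, outcomes, out):
    """Total log-likelihood of one subject's sequence; fills per-trial out.

    choices: 0-based deck per trial; outcomes: scaled net per trial.
    """
    A = params8[0]
    alpha = params8[1]
    c = params8[2]
    lam = params8[3]
    eps_p = params8[4]
    eps_n = params8[5]
    k = params8[6]
    w = params8[7]
    theta = 3.0 ** c - 1.0
    E = np.zeros(4)
    P = np.zeros(4)
    V = np.zeros(4)
    total = 0.0
    T = choices.shape[0]
    for t in range(T):
        if model == VPP:
            for j in range(4):
                V[j] = w * E[j] + (1.0 - w) * P[j]
        else:
            for j in range(4):
                V[j] = E[j]
        m = theta * V[0]
        for j in range(1, 4):
            if theta * V[j] > m:
                m = theta * V[j]
        s = 0.0
        for j in range(4):
            s += math.exp(theta * V[j] - m)
        ch = choices[t]
        lp = theta * V[ch] - m - math.log(s)
        out[t] = lp
        total += lp
        x = outcomes[t]
        if x >= 0.0:
            u = x ** alpha
        else:
            u = -lam * (-x) ** alpha
        if model == PVL_DECAY:
            for j in range(4):
                E[j] = A * E[j]
            E[ch] += u
        else:
            E[ch] += A * (u - E[ch])
        if model == VPP:
            for j in range(4):
                P[j] = k * P[j]
            if x >= 0.0:
                P[ch] += eps_p
            else:
                P[ch] += eps_n
    return total


@njit(cache=True)
def loglik_total(model, params8, choices, outcomes):
    out = np.empty(choices.shape[0])
    return loglik_trials(model, params8, choices, outcomes, out)


@njit(cache=True)
def pointwise_matrix_kernel(model, params_matrix, choices, outcomes, out):
    """Per-draw, per-trial log densities: params_matrix (S, 8) -> out (S, T)."""
    S = params_matrix.shape[0]
    for s in range(S):
        loglik_trials(model, params_matrix[s], choices, outcomes, out[s])


@njit(cache=True)
def simulate_choices(model, params8, net_table, T, seed):
    """Simulate one agent on the task.

    net_table: (4, 60) scaled net outcome per deck and card position;
    draws beyond position 60 recycle the final block of 10 cards.
    Returns (choices 0-based, outcomes, card_indices 1-based).
    """
    np.random.seed(seed)
    A = params8[0]
    alpha = params8[1]
    c = params8[2]
    lam = params8[3]
    eps_p = params8[4]
    eps_n = params8[5]
    k = params8[6]
    w = params8[7]
    theta = 3.0 ** c - 1.0
    E = np.zeros(4)
    P = np.zeros(4)
    V = np.zeros(4)
    prob = np.zeros(4)
    counters = np.zeros(4, dtype=np.int64)
    choices = np.empty(T, dtype=np.int64)
    outcomes = np.empty(T)
    card_idx = np.empty(T, dtype=np.int64)
    n_cards = net_table.shape[1]
    block = 10
    for t in range(T):
        if model == VPP:
            for j in range(4):
                V[j] = w * E[j] + (1.0 - w) * P[j]
        else:
            for j in range(4):
                V[j] = E[j]
        m = theta * V[0]
        for j in range(1, 4):
            if theta * V[j] > m:
                m = theta * V[j]
        s = 0.0
        for j in range(4):
            prob[j] = math.exp(theta * V[j] - m)
            s += prob[j]
        u01 = np.random.random()
        acc = 0.0
        ch = 3
        for j in range(4):
            acc += prob[j] / s
            if u01 < acc:
                ch = j
                break
        counters[ch] += 1
        draw = counters[ch]
        idx = draw - 1
        if idx >= n_cards:
            idx = n_cards - block + (idx - n_cards) % block
        x = net_table[ch, idx]
        choices[t] = ch
        outcomes[t] = x
        card_idx[t] = idx + 1
        if x >= 0.0:
            u = x ** alpha
        else:
            u = -lam * (-x) ** alpha
        if model == PVL_DECAY:
            for j in range(4):
                E[j] = A * E[j]
            E[ch] += u
        else:
            E[ch] += A * (u - E[ch])
        if model == VPP:
            for j in range(4):
                P[j] = k * P[j]
            if x >= 0.0:
                P[ch] += eps_p
            else:
                P[ch] += eps_n
    return choices, outcomes, card_idx


@njit(cache=True)
def run_chain(model, choices, outcomes, kinds, ubounds, mu_prior_sd,
              sigma_upper, n_warmup, n_keep, thin, seed, prior_only):
    """One MCMC chain for the hierarchical model of a single group.

    Subject-level raw parameters get adaptive single-site random-walk
    Metropolis steps (adapted toward 44% acceptance during warmup only);
    group means are updated by their conjugate normal full conditional;
    group SDs by a log-scale random walk restricted to (0, sigma_upper],
    interweaved with a non-centered rescaling move (subjects' raw values
    are rescaled around the group mean along with the proposed SD) that
    decouples the SD from the subject block in the funnel regime.

    Post-warmup, every ``thin``-th sweep is retained until ``n_keep``
    draws are stored. Returns raw-scale draws: (subjects
    (n_keep, n, P), mu (n_keep, P), sigma (n_keep, P)).
    """
    np.random.seed(seed)
    n = choices.shape[0]
    P = kinds.shape[0]

    xi = np.empty((n, P))
    for i in range(n):
        for p in range(P):
            xi[i, p] = 0.1 * np.random.normal()
    mu = np.zeros(P)
    sigma = np.full(P, 0.5)

    step = np.full((n, P), 0.5)
    sstep = np.full(P, 0.5)
    ncstep = np.full(P, 0.3)
    acc = np.zeros((n, P))
    sacc = np.zeros(P)
    ncacc = np.zeros(P)
    xprop = np.empty(n)
    llprop = np.empty(n)

    # per-subject joint proposals along the adapted posterior covariance
    jsum = np.zeros((n, P))
    jsumsq = np.zeros((n, P, P))
    jcount = 0
    jchol = np.zeros((n, P, P))
    have_chol = False
    jscale = np.full(n, 2.38 / math.sqrt(P))
    jacc = np.zeros(n)
    zbuf = np.empty(P)
    rowprop = np.empty(P)
    rowold = np.empty(P)

    nat = np.empty(8)
    ll = np.empty(n)
    for i in range(n):
        to_native8(xi[i], kinds, ubounds, nat)
        ll[i] = 0.0 if prior_only else loglik_total(model, nat, choices[i], outcomes[i])

    subj_out = np.empty((n_keep, n, P))
    mu_out = np.empty((n_keep, P))
    sig_out = np.empty((n_keep, P))

    batch = 0
    for it in range(n_warmup + n_keep * thin):
        for i in range(n):
            for p in range(P):
                old = xi[i, p]
                xi[i, p] = old + step[i, p] * np.random.normal()
                to_native8(xi[i], kinds, ubounds, nat)
                ll_new = 0.0 if prior_only else loglik_total(model, nat, choices[i], outcomes[i])
                d = xi[i, p] - mu[p]
                d0 = old - mu[p]
                log_r = ll_new - ll[i] - (d * d - d0 * d0) / (2.0 * sigma[p] * sigma[p])
                if math.log(np.random.random()) < log_r:
                    ll[i] = ll_new
                    acc[i, p] += 1.0
                else:
                    xi[i, p] = old

        if have_chol:
            for i in range(n):
                for p in range(P):
                    zbuf[p] = np.random.normal()
                    rowold[p] = xi[i, p]
                for p in range(P):
                    move = 0.0
                    for q in range(p + 1):
                        move += jchol[i, p, q] * zbuf[q]
                    rowprop[p] = rowold[p] + jscale[i] * move
                dpr = 0.0
                for p in range(P):
                    d = rowprop[p] - mu[p]
                    d0 = rowold[p] - mu[p]
                    dpr -= (d * d - d0 * d0) / (2.0 * sigma[p] * sigma[p])
                for p in range(P):
                    xi[i, p] = rowprop[p]
                to_native8(xi[i], kinds, ubounds, nat)
                ll_new = 0.0 if prior_only else loglik_total(model, nat, choices[i], outcomes[i])
                if math.log(np.random.random()) < ll_new - ll[i] + dpr:
                    ll[i] = ll_new
                    jacc[i] += 1.0
                else:
                    for p in range(P):
                        xi[i, p] = rowold[p]

        for p in range(P):
            prec = 1.0 / (mu_prior_sd[p] * mu_prior_sd[p]) + n / (sigma[p] * sigma[p])
            total = 0.0
            for i in range(n):
                total += xi[i, p]
            mean = (total / (sigma[p] * sigma[p])) / prec
            mu[p] = mean + np.random.normal() / math.sqrt(prec)

        for p in range(P):
            olds = sigma[p]
            news = olds * math.exp(sstep[p] * np.random.normal())
            if 0.0 < news <= sigma_upper:
                ss = 0.0
                for i in range(n):
                    d = xi[i, p] - mu[p]
                    ss += d * d
                log_r = (-n * math.log(news) - ss / (2.0 * news * news)
                         + n * math.log(olds) + ss / (2.0 * olds * olds)
                         + math.log(news / olds))  # Jacobian of the log walk
                if math.log(np.random.random()) < log_r:
                    sigma[p] = news
                    sacc[p] += 1.0

        # non-centered translation: shift mu and every subject's raw value
        # together (standardised offsets fixed), so the group mean can move
        # even when the group SD is small
        for p in range(P):
            delta = ncstep[p] * np.random.normal()
            newmu = mu[p] + delta
            dll = 0.0
            if prior_only:
                for i in range(n):
                    llprop[i] = 0.0
            else:
                for i in range(n):
                    tmp = xi[i, p]
                    xi[i, p] = tmp + delta
                    to_native8(xi[i], kinds, ubounds, nat)
                    llprop[i] = loglik_total(model, nat, choices[i], outcomes[i])
                    xi[i, p] = tmp
                    dll += llprop[i] - ll[i]
            sd0 = mu_prior_sd[p]
            log_r = dll - (newmu * newmu - mu[p] * mu[p]) / (2.0 * sd0 * sd0)
            if math.log(np.random.random()) < log_r:
                mu[p] = newmu
                for i in range(n):
                    xi[i, p] += delta
                    ll[i] = llprop[i]

        # non-centered rescaling: move sigma while keeping each subject's
        # standardised offset eta_i = (xi_i - mu) / sigma fixed
        for p in range(P):
            olds = sigma[p]
            news = olds * math.exp(ncstep[p] * np.random.normal())
            if 0.0 < news <= sigma_upper:
                for i in range(n):
                    xprop[i] = mu[p] + (xi[i, p] - mu[p]) * news / olds
                dll = 0.0
                if prior_only:
                    for i in range(n):
                        llprop[i] = 0.0
                else:
                    for i in range(n):
                        tmp = xi[i, p]
                        xi[i, p] = xprop[i]
                        to_native8(xi[i], kinds, ubounds, nat)
                        llprop[i] = loglik_total(model, nat, choices[i], outcomes[i])
                        xi[i, p] = tmp
                        dll += llprop[i] - ll[i]
                log_r = dll + math.log(news / olds)  # flat sigma prior + log-walk Jacobian
                if math.log(np.random.random()) < log_r:
                    sigma[p] = news
                    for i in range(n):
                        xi[i, p] = xprop[i]
                        ll[i] = llprop[i]
                    ncacc[p] += 1.0

        if it < n_warmup:
            if it >= 100:
                jcount += 1
                for i in range(n):
                    for p in range(P):
                        jsum[i, p] += xi[i, p]
                        for q in range(P):
                            jsumsq[i, p, q] += xi[i, p] * xi[i, q]
            if jcount >= 100 and (it + 1) % 100 == 0:
                for i in range(n):
                    cov = np.empty((P, P))
                    for p in range(P):
                        mp = jsum[i, p] / jcount
                        for q in range(P):
                            mq = jsum[i, q] / jcount
                            cov[p, q] = jsumsq[i, p, q] / jcount - mp * mq
                    # shrink toward the diagonal and regularise
                    for p in range(P):
                        for q in range(P):
                            if p != q:
                                cov[p, q] *= 0.9
                        cov[p, p] += 1e-6
                    jchol[i] = np.linalg.cholesky(cov)
                have_chol = True
            batch += 1
            if batch == 25:
                for i in range(n):
                    for p in range(P):
                        f = math.exp((acc[i, p] / 25.0 - 0.44) * 0.8)
                        step[i, p] = min(max(step[i, p] * f, 1e-3), 10.0)
                for p in range(P):
                    f = math.exp((sacc[p] / 25.0 - 0.44) * 0.8)
                    sstep[p] = min(max(sstep[p] * f, 1e-3), 10.0)
                    f = math.exp((ncacc[p] / 25.0 - 0.3) * 0.8)
                    ncstep[p] = min(max(ncstep[p] * f, 1e-3), 10.0)
                for i in range(n):
                    f = math.exp((jacc[i] / 25.0 - 0.25) * 0.8)
                    jscale[i] = min(max(jscale[i] * f, 1e-3), 10.0)
                acc[:] = 0.0
                sacc[:] = 0.0
                ncacc[:] = 0.0
                jacc[:] = 0.0
                batch = 0
        elif (it - n_warmup) % thin == thin - 1:
            j = (it - n_warmup) // thin
            for i in range(n):
                for p in range(P):
                    subj_out[j, i, p] = xi[i, p]
            for p in range(P):
                mu_out[j, p] = mu[p]
                sig_out[j, p] = sigma[p]
    return subj_out, mu_out, sig_out
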