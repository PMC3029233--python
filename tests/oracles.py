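"""Independent reference implementations used to certify the HMM code.

Two oracles, both deliberately written in a different style from the
package implementation:

* :func:`enumerate_posterior` — exact posterior by enumerating every
  hidden regime path (normal / variant-continue / variant-redraw) for
  tiny n, scoring each path with closed-form conjugate marginal
  likelihoods.  Exponential cost; usable for n <= 10.
* :class:`UnprunedReference` — an O(n^2) NumPy re-implementation of the
  forward filter and smoother that recomputes every component's
  conjugate posterior non-incrementally from the block of observations
  it spans.  Usable for n around 50.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pscn.hmm import ASSIGNMENT, HmmHyperParams


def _mvn_logpdf(x, mean, cov):
    d = np.asarray(x) - np.asarray(mean)
    cov = np.asarray(cov)
    sign, logdet = np.linalg.slogdet(cov)
    return float(-0.5 * (len(d) * math.log(2 * math.pi) + logdet
                         + d @ np.linalg.inv(cov) @ d))


def _block_posterior(u, g, hp):
    """Conjugate posterior of theta given a variant block of observations.

    Returns (mean, cov, log marginal likelihood) for the block, prior
    N(z, V), emissions A(g_t) theta + N(0, Sigma_{g_t}).
    """
    Vinv = np.linalg.inv(hp.V)
    prec = Vinv.copy()
    lin = Vinv @ hp.z
    Sig = hp.sigma_array()
    for t in range(len(g)):
        A = ASSIGNMENT[g[t]]
        Si = np.linalg.inv(Sig[g[t]])
        prec = prec + A.T @ Si @ A
        lin = lin + A.T @ Si @ u[t]
    cov = np.linalg.inv(prec)
    mean = cov @ lin
    # marginal likelihood via the normalizing-constant ratio
    def _log_gauss_int(prec_, lin_):
        c = np.linalg.inv(prec_)
        m = c @ lin_
        sign, logdet = np.linalg.slogdet(c)
        return 0.5 * (2 * math.log(2 * math.pi) + logdet + lin_ @ m)
    loglik = _log_gauss_int(prec, lin) - _log_gauss_int(Vinv, Vinv @ hp.z)
    for t in range(len(g)):
        A = ASSIGNMENT[g[t]]
        sign, logdet = np.linalg.slogdet(Sig[g[t]])
        loglik += -math.log(2 * math.pi) - 0.5 * logdet \
            - 0.5 * float(u[t] @ np.linalg.inv(Sig[g[t]]) @ u[t])
    return mean, cov, loglik


def enumerate_posterior(u, g, hp: HmmHyperParams):
    """Exact smoother by summing over all hidden regime paths.

    Each path assigns every SNP a regime symbol: 'N' (normal), 'C'
    (variant, continuing the previous variant value) or 'R' (variant,
    value redrawn at this SNP).  'C' is only legal after 'C' or 'R'.

    Returns (theta_hat (n,2), baseline_mass (n,)).
    """
    u = np.asarray(u, dtype=float)
    g = np.asarray(g, dtype=int)
    n = len(g)
    p, r, s = hp.p, hp.r, hp.s
    pi_n = r / (r + p)
    pi_v = p / (r + p)
    Sig = hp.sigma_array()

    def normal_loglik(t):
        A = ASSIGNMENT[g[t]]
        return _mvn_logpdf(u[t], A @ hp.mu0, Sig[g[t]])

    paths = []
    weights = []
    for path in itertools.product("NCR", repeat=n):
        # legality and prior probability
        if path[0] == "C":
            continue
        logprior = math.log(pi_n if path[0] == "N" else pi_v)
        ok = True
        for t in range(1, n):
            a, b = path[t - 1], path[t]
            if a == "N":
                step = {"N": 1 - p, "R": p, "C": 0.0}[b]
            else:
                step = {"N": r, "R": s, "C": 1 - r - s}[b]
            if step <= 0:
                ok = False
                break
            logprior += math.log(step)
        if not ok:
            continue
        # split into normal positions and maximal variant blocks
        loglik = 0.0
        block_info = {}  # t -> (mean, cov) of its block posterior
        t = 0
        while t < n:
            if path[t] == "N":
                loglik += normal_loglik(t)
                t += 1
            else:
                start = t
                t += 1
                while t < n and path[t] == "C":
                    t += 1
                mean, cov, ll = _block_posterior(u[start:t], g[start:t], hp)
                loglik += ll
                for tt in range(start, t):
                    block_info[tt] = (mean, cov)
        paths.append((path, block_info))
        weights.append(logprior + loglik)

    weights = np.array(weights)
    w = np.exp(weights - weights.max())
    w /= w.sum()
    theta = np.zeros((n, 2))
    base = np.zeros(n)
    for (path, blocks), wi in zip(paths, w):
        for t in range(n):
            if path[t] == "N":
                theta[t] += wi * hp.mu0
                base[t] += wi
            else:
                theta[t] += wi * blocks[t][0]
    return theta, base


class UnprunedReference:
    """O(n^2) exact filter/smoother with non-incremental component math."""

    def __init__(self, u, g, hp: HmmHyperParams):
        self.u = np.asarray(u, dtype=float)
        self.g = np.asarray(g, dtype=int)
        self.hp = hp
        self.n = len(self.g)

    def _component(self, j, t):
        """Posterior over theta for a variant block spanning SNPs j..t."""
        return _block_posterior(self.u[j:t + 1], self.g[j:t + 1], self.hp)

    def _predictive(self, j, t):
        """log predictive density of u_t for a block that started at j."""
        hp = self.hp
        A = ASSIGNMENT[self.g[t]]
        Sig = hp.sigma_array()[self.g[t]]
        if j == t:
            mean, cov = hp.z, hp.V
        else:
            mean, cov, _ = self._component(j, t - 1)
        return _mvn_logpdf(self.u[t], A @ mean, A @ cov @ A.T + Sig)

    def forward(self):
        """Normalized weights: list of dicts {'base': w, j: w_j} per t."""
        hp = self.hp
        p, r, s = hp.p, hp.r, hp.s
        pi_n = r / (r + p)
        pi_v = p / (r + p)
        Sig = hp.sigma_array()
        states = []
        for t in range(self.n):
            A = ASSIGNMENT[self.g[t]]
            lbase = _mvn_logpdf(self.u[t], A @ hp.mu0, Sig[self.g[t]])
            if t == 0:
                cand = {"base": math.log(pi_n) + lbase,
                        0: math.log(pi_v) + self._predictive(0, 0)}
            else:
                prev = states[-1]
                sv = sum(v for k, v in prev.items() if k != "base")
                cand = {"base": math.log(prev["base"] * (1 - p) + sv * r)
                        + lbase}
                for j in [k for k in prev if k != "base"]:
                    if prev[j] * (1 - r - s) > 0:
                        cand[j] = math.log(prev[j] * (1 - r - s)) \
                            + self._predictive(j, t)
                cand[t] = math.log(prev["base"] * p + sv * s) \
                    + self._predictive(t, t)
            mx = max(cand.values())
            tot = sum(math.exp(v - mx) for v in cand.values())
            states.append({k: math.exp(v - mx) / tot for k, v in cand.items()})
        return states

    def backward(self):
        rev = UnprunedReference(self.u[::-1], self.g[::-1], self.hp)
        rstates = rev.forward()
        out = []
        for t in range(self.n):
            st = rstates[self.n - 1 - t]
            mapped = {}
            for k, v in st.items():
                mapped[k if k == "base" else self.n - 1 - k] = v
            out.append(mapped)
        return out

    def smooth(self):
        """Exact posterior mean and baseline mass at every SNP."""
        hp = self.hp
        p, r, s = hp.p, hp.r, hp.s
        pi_n = r / (r + p)
        pi_v = p / (r + p)
        fwd = self.forward()
        bwd = self.backward()
        theta = np.zeros((self.n, 2))
        base = np.zeros(self.n)
        for t in range(self.n):
            cand = []  # (log weight, mean)
            if t == self.n - 1:
                st = fwd[t]
                cand.append((math.log(st["base"]) if st["base"] > 0
                             else -np.inf, hp.mu0, True))
                for j in [k for k in st if k != "base"]:
                    mean, _, _ = self._component(j, t)
                    cand.append((math.log(st[j]) if st[j] > 0 else -np.inf,
                                 mean, False))
            else:
                fst, bst = fwd[t], bwd[t + 1]
                sb = sum(v for k, v in bst.items() if k != "base")
                wb = fst["base"] * ((1 - p) * bst["base"] / pi_n
                                    + p * sb / pi_v)
                cand.append((math.log(wb) if wb > 0 else -np.inf,
                             hp.mu0, True))
                fac = r * bst["base"] / pi_n + s * sb / pi_v
                for i in [k for k in fst if k != "base"]:
                    w = fst[i] * fac
                    mean, _, _ = self._component(i, t)
                    cand.append((math.log(w) if w > 0 else -np.inf,
                                 mean, False))
                    for j in [k for k in bst if k != "base"]:
                        if fst[i] <= 0 or bst[j] <= 0:
                            continue
                        # fused block i..j observed on both sides of t
                        mean_f, _, llf = self._component(i, t)
                        mean_b, _, llb = self._component(t + 1, j)
                        mean_j, _, llj = _block_posterior(
                            self.u[i:j + 1], self.g[i:j + 1], self.hp)
                        # weight via marginal-likelihood ratio:
                        # N_i * N_j / prior integrates to ml(i..j)/(ml(i..t)ml(t+1..j))
                        lw = (math.log((1 - r - s) / pi_v)
                              + math.log(fst[i]) + math.log(bst[j])
                              + llj - llf - llb)
                        cand.append((lw, mean_j, False))
            mx = max(c[0] for c in cand)
            tot = sum(math.exp(c[0] - mx) for c in cand)
            for lw, mean, is_base in cand:
                w = math.exp(lw - mx) / tot
                theta[t] += w * np.asarray(mean)
                if is_base:
                    base[t] += w
        return theta, base
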