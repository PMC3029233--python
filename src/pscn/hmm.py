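"""The two-chromosome continuous-state hidden Markov model.

The hidden state ``theta_t = (theta1, theta2)`` is the pair of
parent-specific copy numbers at SNP t.  It follows a reversible
three-state jump process: a *normal* state pinning theta at the diploid
baseline ``mu0``, and two exchangeable *variant* states in which theta
holds a value drawn from the bivariate Gaussian prior N(z, V) at the
time of the jump.  The observation is

    u_t = A(g_t) theta_t + eps_t,    eps_t ~ N(0, Sigma_{g_t}),

where ``A(g)`` is the allele assignment matrix of the inherited genotype
configuration ``g`` (AB = identity, BA = coordinate swap, AA/BB project
both parental copies onto one allele, NP averages the two so only total
intensity is informative).

Conditioned on the genotype track, the filtering distributions are exact
finite Gaussian mixtures indexed by the most recent change-time; the
smoother fuses forward and backward filters by Bayes' rule.  Bounded
complexity (BCMIX) pruning caps the number of retained components, giving
O(n M^2) total cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .io import AA, AB, BA, BB, NP, AlleleSignalTrack

_J = np.array([[0.0, 1.0], [1.0, 0.0]])  # coordinate exchange

#: allele assignment matrices A(g), indexed by genotype code
ASSIGNMENT = np.stack([
    np.array([[1.0, 1.0], [0.0, 0.0]]),   # AA: both copies carry allele A
    np.eye(2),                            # AB
    _J.copy(),                            # BA
    np.array([[0.0, 0.0], [1.0, 1.0]]),   # BB
    np.full((2, 2), 0.5),                 # NP: only total intensity
])


def assignment_matrix(g: int | str) -> np.ndarray:
    """A(g) mapping (theta1, theta2) to expected (x, y)."""
    if isinstance(g, str):
        g = ("AA", "AB", "BA", "BB", "NP").index(g)
    if not 0 <= g <= 4:
        raise ValueError(f"unknown genotype class {g!r}")
    return ASSIGNMENT[g].copy()


def emission_mean(g: int | str, theta) -> np.ndarray:
    """Expected allele intensities for genotype class g at state theta."""
    return assignment_matrix(g) @ np.asarray(theta, dtype=float)


def transition_matrix(p: float, r: float, s: float) -> np.ndarray:
    """3x3 transition matrix over (normal, variant1, variant2).

    From normal the chain leaves with probability p (split evenly over
    the two variant states); from a variant state it returns to normal
    with probability r, jumps to the other variant state with
    probability s, and otherwise keeps its value.  Started from the
    stationary distribution (r/(r+p), p/2(r+p), p/2(r+p)) the chain is
    reversible.  p = 0 (an absorbing normal state) is allowed here,
    though the filters require p > 0.
    """
    _check_rates(p, r, s, allow_zero=True)
    return np.array([
        [1.0 - p, p / 2.0, p / 2.0],
        [r, 1.0 - r - s, s],
        [r, s, 1.0 - r - s],
    ])


def stationary_distribution(p: float, r: float, s: float) -> np.ndarray:
    _check_rates(p, r, s, allow_zero=True)
    return np.array([r / (r + p), p / (2 * (r + p)), p / (2 * (r + p))])


def _check_rates(p, r, s, allow_zero=False):
    lo_ok = (p >= 0 and r >= 0 and p + r > 0) if allow_zero \
        else (p > 0 and r > 0)
    if not (lo_ok and p < 1 and r < 1 and 0 <= s and r + s < 1):
        raise ValueError(f"invalid jump rates p={p}, r={r}, s={s} "
                         "(need 0<p<1, 0<r<1, 0<=s, r+s<1)")


def _default_sigma() -> dict[str, np.ndarray]:
    het = np.diag([0.15 ** 2, 0.15 ** 2])
    hom = np.diag([0.18 ** 2, 0.18 ** 2])
    return {"AA": hom.copy(), "AB": het.copy(), "BA": het.copy(),
            "BB": hom.copy(), "NP": het.copy()}


@dataclass
class HmmHyperParams:
    """Hyperparameters of the two-chromosome HMM.

    mu0 : baseline parent-specific copy numbers, default (1, 1).
    z, V : mean and covariance of the variant-state prior N(z, V).
    sigma : per-genotype-class 2x2 error covariances.
    p : probability of leaving the normal state per SNP step.
    r : variant -> normal probability.
    s : variant -> other-variant probability.
    """

    mu0: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    z: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    V: np.ndarray = field(default_factory=lambda: np.diag([0.36, 0.36]))
    sigma: dict = field(default_factory=_default_sigma)
    p: float = 1e-3
    r: float = 5e-3
    s: float = 1e-4

    def __post_init__(self):
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        _check_rates(self.p, self.r, self.s)
        for name in ("AA", "AB", "BA", "BB"):
            if name not in self.sigma:
                raise ValueError(f"sigma missing class {name}")
        self.sigma = {k: np.asarray(v, dtype=float)
                      for k, v in self.sigma.items()}
        if "NP" not in self.sigma:
            self.sigma["NP"] = self.sigma["AB"].copy()
        for name, m in [("V", self.V)] + list(self.sigma.items()):
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"{name} covariance not positive definite")

    def sigma_array(self) -> np.ndarray:
        return np.stack([self.sigma[c] for c in ("AA", "AB", "BA", "BB", "NP")])

    def swapped_alleles(self) -> "HmmHyperParams":
        """Hyperparameters after exchanging the A/B allele labels."""
        sw = {"AA": _J @ self.sigma["BB"] @ _J, "BB": _J @ self.sigma["AA"] @ _J,
              "AB": _J @ self.sigma["BA"] @ _J, "BA": _J @ self.sigma["AB"] @ _J,
              "NP": _J @ self.sigma["NP"] @ _J}
        return replace(self, sigma=sw)

    def swapped_parents(self) -> "HmmHyperParams":
        """Hyperparameters after relabeling the two parental chromosomes."""
        sw = {"AA": self.sigma["AA"].copy(), "BB": self.sigma["BB"].copy(),
              "AB": self.sigma["BA"].copy(), "BA": self.sigma["AB"].copy(),
              "NP": self.sigma["NP"].copy()}
        return replace(self, mu0=self.mu0[::-1].copy(), z=self.z[::-1].copy(),
                       V=(_J @ self.V @ _J), sigma=sw)


@dataclass
class MixtureFilterState:
    """Filter representation at one SNP: point mass at mu0 + Gaussians."""

    baseline_weight: float
    weights: np.ndarray
    means: np.ndarray       # (m, 2)
    covs: np.ndarray        # (m, 2, 2)
    origin_index: np.ndarray  # change-time of each component

    @property
    def total_weight(self) -> float:
        return float(self.baseline_weight + self.weights.sum())


class FilterStates(Sequence):
    """Sequence of :class:`MixtureFilterState` backed by packed arrays."""

    def __init__(self, fb, fn, fw, fj, fP, fh):
        self.fb, self.fn, self.fw, self.fj, self.fP, self.fh = \
            fb, fn, fw, fj, fP, fh

    def __len__(self):
        return len(self.fb)

    def __getitem__(self, t) -> MixtureFilterState:
        m = int(self.fn[t])
        P = self.fP[t, :m]
        covs = np.empty((m, 2, 2))
        means = np.empty((m, 2))
        for i in range(m):
            prec = np.array([[P[i, 0], P[i, 1]], [P[i, 1], P[i, 2]]])
            covs[i] = np.linalg.inv(prec)
            means[i] = covs[i] @ self.fh[t, i]
        return MixtureFilterState(float(self.fb[t]), self.fw[t, :m].copy(),
                                  means, covs, self.fj[t, :m].copy())


@dataclass
class ParentCopyPosterior:
    """Per-SNP posterior summary of the parent-specific copy numbers."""

    theta_hat: np.ndarray      # (n, 2) posterior means
    baseline_mass: np.ndarray  # (n,) posterior probability of the normal state
    cov: np.ndarray            # (n, 2, 2) posterior covariances

    def __len__(self):
        return len(self.theta_hat)

    @property
    def total(self) -> np.ndarray:
        return self.theta_hat.sum(axis=1)


class FilterNumericalError(RuntimeError):
    pass


def _genotype_codes(g) -> np.ndarray:
    g = np.asarray(g)
    if g.dtype.kind in ("U", "S", "O"):  # string labels
        lut = {"AA": AA, "AB": AB, "BA": BA, "BB": BB, "NP": NP}
        return np.array([lut[str(v)] for v in g], dtype=np.int64)
    return g.astype(np.int64)


def _pack_inputs(hp: HmmHyperParams):
    A = ASSIGNMENT
    Apack = A.reshape(5, 4).copy()
    Sig_full = hp.sigma_array()
    Siginv_full = np.linalg.inv(Sig_full)
    Sig = Sig_full[:, [0, 0, 1], [0, 1, 1]].copy()
    Siginv = Siginv_full[:, [0, 0, 1], [0, 1, 1]].copy()
    logdetSig = np.log(np.linalg.det(Sig_full))
    Bfull = np.einsum("cji,cjk,ckl->cil", A, Siginv_full, A)
    B = Bfull[:, [0, 0, 1], [0, 1, 1]].copy()
    ASi = np.einsum("cji,cjk->cik", A, Siginv_full).reshape(5, 4).copy()
    Vinv_full = np.linalg.inv(hp.V)
    V = hp.V[[0, 0, 1], [0, 1, 1]].copy()
    Vinv = Vinv_full[[0, 0, 1], [0, 1, 1]].copy()
    return Apack, Sig, Siginv, logdetSig, B, ASi, V, Vinv


def _run_forward(u, codes, hp, M, K):
    Apack, Sig, Siginv, logdetSig, B, ASi, V, Vinv = _pack_inputs(hp)
    out = _kernels.forward_kernel(
        np.ascontiguousarray(u, dtype=np.float64), codes, Apack, Sig, Siginv,
        logdetSig, B, ASi, hp.mu0, hp.z, V, Vinv,
        float(hp.p), float(hp.r), float(hp.s), int(M), int(K))
    fb, fn, fw, fj, fP, fh, err = out
    if err[0] >= 0:
        raise FilterNumericalError(
            f"filter update failed at SNP index {int(err[0])} "
            "(singular or degenerate covariance)")
    return fb, fn, fw, fj, fP, fh


def forward_filter(track: AlleleSignalTrack, g, hp: HmmHyperParams,
                   M: int = 20, K: int = 10) -> FilterStates:
    """Forward filter P(theta_t | u_{1..t}, g) at every SNP."""
    codes = _genotype_codes(g)
    return FilterStates(*_run_forward(track.u, codes, hp, M, K))


def backward_filter(track: AlleleSignalTrack, g, hp: HmmHyperParams,
                    M: int = 20, K: int = 10) -> FilterStates:
    """Backward filter P(theta_t | u_{t..n}, g).

    By reversibility of the state chain this is the forward filter run on
    the index-reversed sequence, re-reversed.
    """
    codes = _genotype_codes(g)[::-1].copy()
    fb, fn, fw, fj, fP, fh = _run_forward(track.u[::-1], codes, hp, M, K)
    n = len(fb)
    # map change-times back to original coordinates
    fj = (n - 1) - fj
    return FilterStates(fb[::-1].copy(), fn[::-1].copy(), fw[::-1].copy(),
                        fj[::-1].copy(), fP[::-1].copy(), fh[::-1].copy())


def smooth(track: AlleleSignalTrack, g, hp: HmmHyperParams,
           M: int = 20, K: int = 10) -> ParentCopyPosterior:
    """Posterior mean E(theta_t | u_{1..n}, g) via forward/backward fusion."""
    codes = _genotype_codes(g)
    u = track.u
    fb, fn, fw, fj, fP, fh = _run_forward(u, codes, hp, M, K)
    rb, rn, rw, rj, rP, rh = _run_forward(u[::-1],
                                          codes[::-1].copy(), hp, M, K)
    bb = rb[::-1].copy()
    bn = rn[::-1].copy()
    bw = rw[::-1].copy()
    bP = rP[::-1].copy()
    bh = rh[::-1].copy()
    Vinv_full = np.linalg.inv(hp.V)
    Vinv = Vinv_full[[0, 0, 1], [0, 1, 1]].copy()
    theta, base_mass, covp = _kernels.smooth_kernel(
        fb, fn, fw, fP, fh, bb, bn, bw, bP, bh,
        hp.mu0, hp.z, Vinv, float(hp.p), float(hp.r), float(hp.s))
    cov = np.empty((len(theta), 2, 2))
    cov[:, 0, 0] = covp[:, 0]
    cov[:, 0, 1] = cov[:, 1, 0] = covp[:, 1]
    cov[:, 1, 1] = covp[:, 2]
    return ParentCopyPosterior(theta, base_mass, cov)
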