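"""Model/Results interface: allele-specific iterative smoothing.

:class:`PscnModel` wraps one chromosome of allele-specific signals and
fits the two-chromosome HMM by alternating

* E-step — posterior-mean parent-specific copy numbers given the current
  genotype configurations (the mixture smoother of :mod:`pscn.hmm`), and
* M-step — per-SNP maximum a posteriori genotype configurations given the
  copy numbers (a four-component Gaussian mixture decode),

re-estimating the hyperparameters from the current fit each round.  The
resulting posterior-mean track is hard-segmented by Euclidean contrast
of windowed (major, minor)-sorted means with rank-sum merging, and each
segment is classified by :mod:`pscn.classify`.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter

from . import classify as _classify
from .config import RunConfig
from .hmm import (ASSIGNMENT, HmmHyperParams, ParentCopyPosterior,
                  _genotype_codes, smooth)
from .io import AA, AB, BA, BB, NP, AlleleSignalTrack, GenotypePrior

logger = logging.getLogger(__name__)

GENOTYPE_LABELS = np.array(["AA", "AB", "BA", "BB", "NP"])


class DegenerateClusteringError(ValueError):
    pass


def _lloyd4(pts: np.ndarray, max_iter: int = 100):
    """Deterministic 4-center Lloyd clustering of (x, y) intensities.

    Centers start from the canonical genotype geometry (homozygous
    corners, two central heterozygote positions) scaled to the data's
    mean total intensity.  Initialization is independent of the point
    order and symmetric under an x/y exchange, which makes the whole
    genotype seeding reversal-invariant and allele-swap-equivariant.
    """
    scale = max(float(np.mean(pts.sum(axis=1))) / 2.0, 1e-6)
    centers = scale * np.array([[2.0, 0.0], [1.2, 0.8],
                                [0.8, 1.2], [0.0, 2.0]])
    lab = None
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_lab = np.argmin(d2, axis=1)
        if lab is not None and np.array_equal(new_lab, lab):
            break
        lab = new_lab
        for c in range(4):
            sel = lab == c
            if sel.any():
                centers[c] = pts[sel].mean(axis=0)
    return lab, centers


@dataclass
class IterationTrace:
    """Convergence diagnostics of the E/M alternation."""

    change_norms: list = field(default_factory=list)
    genotype_flips: list = field(default_factory=list)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.change_norms)


@dataclass
class ChangePointSet:
    """Sorted boundary indices (between SNP b and b+1) with their jumps."""

    indices: np.ndarray
    distances: np.ndarray

    def __len__(self):
        return len(self.indices)

    def segments(self, n: int) -> list[tuple[int, int]]:
        """Inclusive (start, end) SNP index ranges of the segmentation."""
        bounds = [-1] + list(self.indices) + [n - 1]
        return [(bounds[k] + 1, bounds[k + 1])
                for k in range(len(bounds) - 1)]


# ---------------------------------------------------------------------------
# genotype initialization and M-step
# ---------------------------------------------------------------------------

def initialize_genotypes(track: AlleleSignalTrack, priors: GenotypePrior,
                         seed: int = 0) -> np.ndarray:
    """Initial genotype configurations by 4-group clustering of (x, y).

    Clusters are mapped to labels by centroid geometry (extreme x/y ratio
    clusters become the homozygotes); the two heterozygous clusters are
    split uniformly at random between AB and BA, which are exchangeable
    before any copy-number asymmetry has been estimated.  The coin flip
    is a per-SNP hash of (seed, snp_id) XOR the sign of x - y: uniform
    and independent of the noise, yet stable under re-ordering of the
    track and flipping deterministically under an A/B label swap.  NP
    markers and zero-prior labels are respected.
    """
    xy = track.u
    poly = ~priors.non_polymorphic
    pts = xy[poly]
    if len(np.unique(pts, axis=0)) < 4:
        raise DegenerateClusteringError(
            "fewer than 4 distinct intensity points; cannot seed genotypes")
    lab, centers = _lloyd4(pts)
    # map centroids to zygosity by the angle of (x, y): A-rich sectors
    # are homozygous AA, B-rich BB, the middle heterozygous.  Sector
    # thresholds (rather than rank order) tolerate the clustering
    # splitting a large homozygote cloud into two clusters.
    ang = np.arctan2(centers[:, 1], centers[:, 0])
    remap = np.full(4, -1, dtype=np.int64)  # -1: heterozygous
    remap[ang < np.pi / 8] = AA
    remap[ang > 3 * np.pi / 8] = BB
    if (remap == -1).sum() == 0:
        # degenerate geometry: fall back to rank order so the two
        # central clusters are still treated as heterozygous
        order = np.argsort(ang)
        remap[order[1:3]] = -1
    g_poly = remap[lab]
    het = g_poly == -1
    ids = track.snp_id[poly][het]
    bits = np.array([zlib.crc32(f"{seed}|{sid}".encode()) & 1
                     for sid in ids], dtype=bool)
    g_poly[het] = np.where(bits ^ (pts[het, 0] < pts[het, 1]), BA, AB)

    g = np.full(len(track), NP, dtype=np.int64)
    g[poly] = g_poly
    # never assign a label the prior excludes
    probs = priors.probs
    bad = poly & (probs[np.arange(len(track)), np.clip(g, 0, 3)] <= 0)
    if bad.any():
        g[bad] = np.argmax(probs[bad], axis=1)
    return g


def genotype_mstep(track: AlleleSignalTrack, theta_hat: np.ndarray,
                   priors: GenotypePrior, hp: HmmHyperParams) -> np.ndarray:
    """Per-SNP MAP genotype configuration given the copy-number track.

    For each SNP independently, maximizes prior times bivariate normal
    density of u_t with mean A(g) theta_t and covariance Sigma_g.  Ties
    break by fixed class order (AA, AB, BA, BB).
    """
    u = track.u
    n = len(track)
    Sig = hp.sigma_array()
    Siginv = np.linalg.inv(Sig)
    logdet = np.log(np.linalg.det(Sig))
    scores = np.full((n, 4), -np.inf)
    with np.errstate(divide="ignore"):
        logprior = np.log(priors.probs)
    for c in range(4):
        mean = theta_hat @ ASSIGNMENT[c].T
        d = u - mean
        quad = (Siginv[c, 0, 0] * d[:, 0] ** 2
                + 2 * Siginv[c, 0, 1] * d[:, 0] * d[:, 1]
                + Siginv[c, 1, 1] * d[:, 1] ** 2)
        scores[:, c] = logprior[:, c] - 0.5 * (logdet[c] + quad)
    g = np.argmax(scores, axis=1)  # first max wins: AA < AB < BA < BB
    g[priors.non_polymorphic] = NP
    return g.astype(np.int64)


# ---------------------------------------------------------------------------
# hyperparameter estimation
# ---------------------------------------------------------------------------

def _deviation_runs(dev: np.ndarray, gap: int = 10,
                    min_run: int = 10) -> list[tuple[int, int]]:
    """Maximal excursion runs, bridging short gaps and dropping stubs.

    Isolated deviating SNPs are genotyping artifacts rather than copy
    number events; only consolidated runs inform the jump rates.
    """
    idx = np.flatnonzero(np.diff(np.r_[0, dev.astype(np.int8), 0]))
    runs = list(zip(idx[::2], idx[1::2]))  # half-open [a, b)
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a >= min_run]


def estimate_hyperparams(track: AlleleSignalTrack, theta_hat: np.ndarray,
                         g, previous: HmmHyperParams,
                         baseline_mass: np.ndarray | None = None,
                         ) -> HmmHyperParams:
    """Method-of-moments update of the HMM hyperparameters.

    Error covariances come from per-class residuals (shrunk toward the
    pooled covariance for thin classes); the variant prior (z, V) from
    the posterior means of SNPs inside consolidated excursions of
    theta_hat away from mu0; the jump rates from the entry/exit counts
    of those excursions.  Rates are clipped to [1e-6, 0.2]; s is kept
    fixed.
    """
    codes = _genotype_codes(g)
    u = track.u
    resid = u - np.einsum("tij,tj->ti", ASSIGNMENT[codes], theta_hat)
    pooled = np.cov(resid.T) + 1e-6 * np.eye(2)
    sigma = {}
    for c, name in zip(range(5), ("AA", "AB", "BA", "BB", "NP")):
        mask = codes == c
        nc = int(mask.sum())
        if nc < 5:
            sigma[name] = pooled.copy()
            continue
        S = np.cov(resid[mask].T) + 1e-6 * np.eye(2)
        if nc < 50:
            S = 0.9 * S + 0.1 * pooled
        sigma[name] = S
    # exchange symmetry of the heterozygous classes
    J = np.array([[0.0, 1.0], [1.0, 0.0]])
    ab = 0.5 * (sigma["AB"] + J @ sigma["BA"] @ J)
    sigma["AB"] = ab
    sigma["BA"] = J @ ab @ J
    if (codes == NP).sum() < 50:
        sigma["NP"] = sigma["AB"].copy()

    hp = replace(previous, sigma=sigma)

    dev = np.linalg.norm(theta_hat - previous.mu0, axis=1) > 0.2
    runs = _deviation_runs(dev)
    run_mask = np.zeros(len(theta_hat), dtype=bool)
    for a, b in runs:
        run_mask[a:b] = True
    variant = run_mask
    if baseline_mass is not None:
        variant = variant & (baseline_mass < 0.5)
    nv = int(variant.sum())
    if nv >= 20:
        z = theta_hat[variant].mean(axis=0)
        V = np.cov(theta_hat[variant].T) + 1e-4 * np.eye(2)
        hp = replace(hp, z=z, V=V)

    if runs:
        n_dev = int(run_mask.sum())
        n_norm = len(theta_hat) - n_dev
        entries = sum(1 for a, b in runs if a > 0)
        exits = sum(1 for a, b in runs if b < len(theta_hat))
        p = np.clip(entries / max(n_norm, 1), 1e-6, 0.2)
        r = np.clip(exits / max(n_dev, 1), 1e-6, 0.2)
        hp = replace(hp, p=float(p), r=float(r))
    return hp


# ---------------------------------------------------------------------------
# hard segmentation
# ---------------------------------------------------------------------------

def _imbalance_candidates(track: AlleleSignalTrack, min_sep: int,
                          z_threshold: float = 5.0) -> np.ndarray:
    """Boundary candidates from raw allelic-imbalance contrast.

    Copy-neutral LOH at very low contamination is invisible to the
    posterior means: with every SNP labelled homozygous the region
    matches the baseline emission exactly, and only the *absence of
    heterozygotes* — a shift in |x - y| — marks it.  A wide windowed
    mean contrast of |x - y|, standardized by its sampling error,
    proposes boundaries; the rank-sum merge re-tests each one, so this
    channel only needs to nominate, not to decide.
    """
    imbal = np.abs(track.x - track.y)
    n = len(imbal)
    w = min(10 * min_sep, max(1, (n - 1) // 2))
    cs = np.r_[0.0, np.cumsum(imbal)]
    cs2 = np.r_[0.0, np.cumsum(imbal ** 2)]
    z = np.zeros(n - 1)
    t = np.arange(w - 1, n - w)
    left = (cs[t + 1] - cs[t + 1 - w]) / w
    right = (cs[t + 1 + w] - cs[t + 1]) / w
    var_l = (cs2[t + 1] - cs2[t + 1 - w]) / w - left ** 2
    var_r = (cs2[t + 1 + w] - cs2[t + 1]) / w - right ** 2
    se = np.sqrt(np.maximum(var_l + var_r, 1e-12) / w)
    z[t] = np.abs(right - left) / se
    peak = np.r_[z[:-1] >= z[1:], True] & np.r_[True, z[1:] > z[:-1]]
    cand = np.flatnonzero((z > z_threshold) & peak)
    cand = cand[(cand >= min_sep - 1) & (cand <= n - 1 - min_sep)]
    cand = cand[np.argsort(-z[cand], kind="stable")]
    # one nomination per window-width: secondary peaks of the same bump
    # would carve self-selected mini-segments out of noise
    kept: list[int] = []
    for b in cand:
        if all(abs(int(b) - k) >= w for k in kept):
            kept.append(int(b))
    return np.array(sorted(kept), dtype=np.int64)


def hard_segment(theta_posterior, threshold: float = 0.1,
                 min_sep: int = 20,
                 track: AlleleSignalTrack | None = None) -> ChangePointSet:
    """Greedy changepoint picking on one-step Euclidean distances.

    Starting from the sequence end points, repeatedly adds the boundary
    with the largest contrast d_t exceeding ``threshold`` among
    boundaries at least ``min_sep`` SNPs from every accepted boundary
    (and the ends), until none qualifies.  Ties break toward the
    smallest index.

    Two robustness choices in the distance itself:

    * it is computed on the per-SNP (major, minor)-sorted posterior
      means — the parental chromosomes are exchangeable, so a swap of
      the arbitrary orientation between adjacent SNPs is not a copy
      number change and must not spawn a boundary;
    * it contrasts ``min_sep``-SNP means on either side of the boundary
      rather than single SNPs: at high normal-cell contamination the
      posterior mean ramps over tens of SNPs at a true boundary, and
      only the aggregated step crosses a useful threshold.
    """
    theta = theta_posterior.theta_hat if hasattr(theta_posterior, "theta_hat") \
        else np.asarray(theta_posterior, dtype=float)
    n = len(theta)
    srt = np.sort(theta, axis=1)[:, ::-1]
    w = min(min_sep, max(1, (n - 1) // 2))
    cs = np.vstack([np.zeros(2), np.cumsum(srt, axis=0)])
    d = np.zeros(n - 1)
    t = np.arange(w - 1, n - w)
    left = (cs[t + 1] - cs[t + 1 - w]) / w
    right = (cs[t + 1 + w] - cs[t + 1]) / w
    d[t] = np.linalg.norm(right - left, axis=1)
    # candidates are local maxima of the contrast profile above the
    # threshold: a strong boundary raises d over a whole window, but
    # only its peak marks the changepoint
    peak = np.r_[d[:-1] >= d[1:], True] & np.r_[True, d[1:] > d[:-1]]
    cand = np.flatnonzero((d > threshold) & peak)
    # boundary b must leave >= min_sep SNPs on each side of the sequence
    cand = cand[(cand >= min_sep - 1) & (cand <= n - 1 - min_sep)]
    order = cand[np.lexsort((cand, -d[cand]))]
    accepted: list[int] = []
    for b in order:
        if all(abs(b - a) >= min_sep for a in accepted):
            accepted.append(int(b))
    if track is not None:
        for b in _imbalance_candidates(track, min_sep):
            if all(abs(b - a) >= min_sep for a in accepted):
                accepted.append(int(b))
    accepted.sort()
    idx = np.array(accepted, dtype=np.int64)
    return ChangePointSet(idx, d[idx] if len(idx) else np.empty(0))


def merge_segments(track: AlleleSignalTrack, changepoints: ChangePointSet,
                   alpha: float = 1e-4) -> ChangePointSet:
    """Remove boundaries whose flanking segments are indistinguishable.

    Two two-sided Wilcoxon rank-sum tests per adjacent pair — on total
    intensity (x+y) and on allelic-imbalance magnitude |x-y| — and the
    boundary is dropped when both p-values exceed ``alpha``.  The
    imbalance test is what defends copy-neutral LOH boundaries, where the
    totals agree.  Least significant boundaries are removed first, until
    stable.
    """
    n = len(track)
    total = track.x + track.y
    imbal = np.abs(track.x - track.y)
    bounds = list(changepoints.indices)
    d_at = dict(zip(changepoints.indices, changepoints.distances))

    def segs(bs):
        edges = [-1] + list(bs) + [n - 1]
        return [(edges[k] + 1, edges[k + 1]) for k in range(len(edges) - 1)]

    # segments with < 2 SNPs merge into a neighbor unconditionally
    changed = True
    while changed:
        changed = False
        for k, (a, b) in enumerate(segs(bounds)):
            if b - a + 1 < 2 and bounds:
                drop = bounds[k] if k < len(bounds) else bounds[k - 1]
                bounds.remove(drop)
                changed = True
                break

    def summary(a, b):
        return (float(np.mean(total[a:b + 1])),
                float(np.mean(imbal[a:b + 1])))

    # p-values are cached per boundary; a removal only invalidates the
    # two boundaries now adjacent to the merged segment
    pcache: dict[tuple[int, int, int], tuple[float, float]] = {}

    def boundary_p(la, lb, ra, rb):
        key = (la, lb, rb)
        if key not in pcache:
            p_tot = stats.ranksums(total[la:lb + 1],
                                   total[ra:rb + 1]).pvalue
            p_imb = stats.ranksums(imbal[la:lb + 1],
                                   imbal[ra:rb + 1]).pvalue
            pcache[key] = (p_tot, p_imb)
        return pcache[key]

    while bounds:
        seg_list = segs(bounds)
        seg_len = [b - a + 1 for a, b in seg_list]
        removable = set()
        for k in range(len(bounds)):
            la, lb = seg_list[k]
            ra, rb = seg_list[k + 1]
            p_tot, p_imb = boundary_p(la, lb, ra, rb)
            if p_tot > alpha and p_imb > alpha:
                removable.add(k)
        if not removable:
            break
        # absorb the shortest mergeable segment first: fragments of a
        # region must consolidate before its true boundary is judged at
        # full power
        k_star = min(removable,
                     key=lambda k: (min(seg_len[k], seg_len[k + 1]), k))
        frag = k_star if seg_len[k_star] <= seg_len[k_star + 1] \
            else k_star + 1
        # boundaries flanking the fragment segment (as bound indices)
        options = [k for k in (frag - 1, frag)
                   if 0 <= k < len(bounds) and k in removable]
        if len(options) > 1:
            # merge toward the more similar neighbor by segment-mean
            # (total, imbalance)
            fs = np.array(summary(*seg_list[frag]))

            def neighbor_dist(k):
                nb = seg_list[frag - 1] if k == frag - 1 \
                    else seg_list[frag + 1]
                return float(np.abs(fs - np.array(summary(*nb))).sum())

            options.sort(key=neighbor_dist)
        del bounds[options[0]]
    idx = np.array(bounds, dtype=np.int64)
    return ChangePointSet(idx, np.array([d_at.get(b, np.nan) for b in idx]))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PscnModel:
    """Parent-specific copy number model for one chromosome.

    Parameters
    ----------
    track : AlleleSignalTrack
        Ordered per-SNP allele intensities.
    priors : GenotypePrior, optional
        Per-SNP genotype configuration priors; uniform if omitted.
    known_genotypes : array-like, optional
        Genotype configurations from a matched normal sample.  When
        given, the M-step is skipped and only copy numbers are estimated.
    config : RunConfig, optional
        Tuning parameters (tolerances, BCMIX sizes, thresholds).
    """

    def __init__(self, track: AlleleSignalTrack,
                 priors: GenotypePrior | None = None,
                 known_genotypes=None,
                 config: RunConfig | None = None):
        self.track = track
        self.priors = priors if priors is not None \
            else GenotypePrior.uniform(len(track))
        if len(self.priors) != len(track):
            raise ValueError("priors and track length mismatch")
        self.known_genotypes = None if known_genotypes is None \
            else _genotype_codes(known_genotypes)
        self.config = config or RunConfig()
        if len(track) < 2 * self.config.min_sep:
            raise ValueError(
                f"track of {len(track)} SNPs is shorter than "
                f"2*min_sep = {2 * self.config.min_sep}")

    @classmethod
    def from_dataframe(cls, df, chrom=None, **kwargs) -> "PscnModel":
        """Build from a DataFrame in the on-disk TSV dialect."""
        from .io import read_snp_table
        import io as _io
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        tracks = read_snp_table(buf)
        if chrom is None:
            if len(tracks) != 1:
                raise ValueError("multiple chromosomes; pass chrom=")
            chrom = next(iter(tracks))
        return cls(tracks[str(chrom)], **kwargs)

    def fit(self, hp0: HmmHyperParams | None = None, seed: int = 0,
            classify: bool = True) -> "PscnResults":
        cfg = self.config
        hp = hp0 or HmmHyperParams()
        if self.known_genotypes is not None:
            g = self.known_genotypes.copy()
        else:
            g = initialize_genotypes(self.track, self.priors, seed=seed)

        trace = IterationTrace()
        theta_prev = np.tile(hp.mu0, (len(self.track), 1))
        post = None
        for k in range(cfg.max_iter):
            post = smooth(self.track, g, hp, M=cfg.bcmix_M, K=cfg.bcmix_K)
            delta = float(np.linalg.norm(
                post.theta_hat - theta_prev, axis=1).sum() / len(self.track))
            theta_prev = post.theta_hat
            flips = 0
            if self.known_genotypes is None:
                # a rolling median of theta_hat feeds the M-step: copy
                # number is constant over >= min_sep SNPs, and the
                # filtering stops single mislabeled SNPs from justifying
                # their own one-SNP copy-number excursion
                theta_m = np.column_stack([
                    median_filter(post.theta_hat[:, 0], 9, mode="nearest"),
                    median_filter(post.theta_hat[:, 1], 9, mode="nearest")])
                g_new = genotype_mstep(self.track, theta_m,
                                       self.priors, hp)
                flips = int((g_new != g).sum())
                g = g_new
            hp = estimate_hyperparams(self.track, post.theta_hat, g, hp,
                                      baseline_mass=post.baseline_mass)
            trace.change_norms.append(delta)
            trace.genotype_flips.append(flips)
            if delta < cfg.tol:
                trace.converged = True
                break
            # secondary stop: genotypes stable and theta_hat nearly so.
            # Inside complete LOH the parent split is unidentifiable and
            # theta_hat can wander in that null space without ever
            # meeting the primary tolerance.
            if (k >= 3 and flips <= max(1, round(2e-4 * len(self.track)))
                    and delta < 50 * cfg.tol):
                trace.converged = True
                break
        if not trace.converged:
            logger.warning("E/M alternation not converged after %d "
                           "iterations (last change %.2e)", trace.n_iter,
                           trace.change_norms[-1])

        cps = hard_segment(post, cfg.d_threshold, cfg.min_sep,
                           track=self.track)
        cps = merge_segments(self.track, cps, cfg.wilcoxon_alpha)
        segments = None
        if classify:
            segments = _classify.classify_segments(
                self.track, g, post, cps, self.priors,
                alpha=cfg.alpha, min_effect=cfg.min_effect,
                loh_flag_threshold=cfg.loh_flag_threshold)
        return PscnResults(self, post, g, hp, trace, cps, segments)


class PscnResults:
    """Fit results: posterior copy numbers, genotypes, segments."""

    def __init__(self, model, posterior: ParentCopyPosterior, genotypes,
                 hyperparams: HmmHyperParams, trace: IterationTrace,
                 changepoints: ChangePointSet, segments):
        self.model = model
        self.posterior = posterior
        self.genotypes = np.asarray(genotypes)
        self.hyperparams = hyperparams
        self.trace = trace
        self.changepoints = changepoints
        self.segments = segments

    @property
    def track(self) -> AlleleSignalTrack:
        return self.model.track

    @property
    def theta_hat(self) -> np.ndarray:
        return self.posterior.theta_hat

    @property
    def genotype_labels(self) -> np.ndarray:
        return GENOTYPE_LABELS[self.genotypes]

    def to_frame(self):
        import pandas as pd
        t = self.track
        return pd.DataFrame({
            "snp_id": t.snp_id, "chrom": t.chrom, "pos": t.pos,
            "x": t.x, "y": t.y,
            "theta1": self.theta_hat[:, 0], "theta2": self.theta_hat[:, 1],
            "baseline_mass": self.posterior.baseline_mass,
            "genotype": self.genotype_labels,
        })

    def segments_frame(self):
        import pandas as pd
        rows = [s.to_dict() for s in (self.segments or [])]
        return pd.DataFrame(rows, columns=_classify.SEGMENT_COLUMNS)

    def summary(self) -> str:
        t = self.track
        lines = [
            "Parent-specific copy number fit",
            "=" * 46,
            f"chromosome {t.chrom}: {len(t)} SNPs, "
            f"{t.pos[0]}-{t.pos[-1]}",
            f"iterations: {self.trace.n_iter} "
            f"(converged: {self.trace.converged})",
            f"jump rates: p={self.hyperparams.p:.2e} "
            f"r={self.hyperparams.r:.2e} s={self.hyperparams.s:.2e}",
            f"breakpoints: {len(self.changepoints)}",
        ]
        if self.segments is not None:
            lines.append(f"segments: {len(self.segments)}")
            lines.append("-" * 46)
            lines.append(f"{'start':>10} {'end':>10} {'major':>6} "
                         f"{'minor':>6}  label")
            for s in self.segments:
                lines.append(f"{s.start_pos:>10} {s.end_pos:>10} "
                             f"{s.fit.mu_major:>6.2f} {s.fit.mu_minor:>6.2f}"
                             f"  {s.label}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Minimal segment plot: per-SNP theta_hat with segment labels."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        idx = np.arange(len(self.track))
        ax.plot(idx, self.theta_hat[:, 0], ".", ms=1, label="parent 1")
        ax.plot(idx, self.theta_hat[:, 1], ".", ms=1, label="parent 2")
        for b in self.changepoints.indices:
            ax.axvline(b + 0.5, color="gray", lw=0.5)
        ax.set_xlabel("SNP index")
        ax.set_ylabel("copy number")
        ax.legend(loc="upper right", fontsize="small")
        return ax
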