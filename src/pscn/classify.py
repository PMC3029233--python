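"""Post-segmentation region characterization.

For each segment the copy numbers of the more and less abundant parental
chromosome ("major" and "minor") are estimated from the heterozygous
SNPs by a two-component swap-mixture EM; Welch t-tests with a Bonferroni
correction compare major, minor and total against the pooled normal
baseline; and each segment receives one of seven labels:

    normal, gain/gain, gain/normal, balanced gain/loss,
    unbalanced gain/loss, normal/loss, loss/loss.

"Balanced" gain/loss (copy-neutral LOH) is the case where major and
minor deviate in opposite directions while the total stays at the
baseline.  Segments with minor near zero are additionally scored for the
probability that the apparent LOH is inherited rather than somatic,
using an independence approximation over the per-SNP heterozygosity
priors; the flag is recorded but never deletes a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AB, BA, AlleleSignalTrack, GenotypePrior

LABELS = ("normal", "gain/gain", "gain/normal", "balanced gain/loss",
          "unbalanced gain/loss", "normal/loss", "loss/loss")

SEGMENT_COLUMNS = ["chrom", "start", "end", "n_snps", "n_het", "major",
                   "minor", "total", "label", "p_major", "p_minor",
                   "p_total", "inherited_loh_prob"]


class EmDivergenceError(RuntimeError):
    pass


class BaselineError(ValueError):
    """No normal segments to pool a baseline from."""


@dataclass
class RegionMixtureFit:
    """Major/minor copy-number estimates for one segment."""

    mu_major: float
    mu_minor: float
    sigma_major: float
    sigma_minor: float
    mix_p: float
    n_het: int
    loglik_trace: list = field(default_factory=list)
    confidence: str = "ok"


@dataclass
class BaselineSummary:
    """Pooled per-allele level of the segments at normal state."""

    mu: float
    sigma: float
    n: int


@dataclass
class SegmentTests:
    t_major: float
    t_minor: float
    t_total: float
    p_major: float
    p_minor: float
    p_total: float
    e_major: float = 0.0   # mu_major - baseline per-allele level
    e_minor: float = 0.0
    e_total: float = 0.0   # (major + minor) - baseline total


@dataclass
class SegmentCall:
    chrom: str
    start_pos: int
    end_pos: int
    start_index: int
    end_index: int
    fit: RegionMixtureFit
    tests: SegmentTests
    label: str
    inherited_loh_prob: float | None = None
    loh_flagged: bool = False

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index + 1

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "start": self.start_pos,
            "end": self.end_pos, "n_snps": self.n_snps,
            "n_het": self.fit.n_het,
            "major": self.fit.mu_major, "minor": self.fit.mu_minor,
            "total": self.fit.mu_major + self.fit.mu_minor,
            "label": self.label,
            "p_major": self.tests.p_major, "p_minor": self.tests.p_minor,
            "p_total": self.tests.p_total,
            "inherited_loh_prob": (np.nan if self.inherited_loh_prob is None
                                   else self.inherited_loh_prob),
        }


def fit_region_mixture(het_xy: np.ndarray, eps: float = 1e-6,
                       max_iter: int = 500) -> RegionMixtureFit:
    """Two-component swap-mixture EM on the heterozygous SNPs of a segment.

    Each heterozygous SNP's (x, y) is (major, minor) with probability
    ``mix_p`` and (minor, major) otherwise, Gaussian per coordinate.
    Initialization: means 1.1 and 0.9 (a small split around the diploid
    level), mixture weight 0.5, unit standard deviations.  Stops when
    the largest absolute parameter change falls below ``eps``.  The
    result is swap-normalized so mu_major >= mu_minor.
    """
    xy = np.asarray(het_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("het_xy must be (n, 2)")
    n = len(xy)
    if n < 10:
        raise ValueError("need at least 10 heterozygous SNPs "
                         "(use the pooled fallback below that)")
    x, y = xy[:, 0], xy[:, 1]
    mu1, mu2, s1, s2, mp = 1.1, 0.9, 1.0, 1.0, 0.5
    trace = []
    for _ in range(max_iter):
        l1 = (stats.norm.logpdf(x, mu1, s1) + stats.norm.logpdf(y, mu2, s2)
              + np.log(mp))
        l2 = (stats.norm.logpdf(x, mu2, s2) + stats.norm.logpdf(y, mu1, s1)
              + np.log1p(-mp))
        mx = np.maximum(l1, l2)
        ll = float(np.sum(mx + np.log(np.exp(l1 - mx) + np.exp(l2 - mx))))
        trace.append(ll)
        gam = 1.0 / (1.0 + np.exp(l2 - l1))
        mu1_new = float(np.mean(gam * x + (1 - gam) * y))
        mu2_new = float(np.mean(gam * y + (1 - gam) * x))
        s1_new = float(np.sqrt(np.mean(gam * (x - mu1_new) ** 2
                                       + (1 - gam) * (y - mu1_new) ** 2)))
        s2_new = float(np.sqrt(np.mean(gam * (y - mu2_new) ** 2
                                       + (1 - gam) * (x - mu2_new) ** 2)))
        mp_new = float(np.clip(np.mean(gam), 1e-6, 1 - 1e-6))
        s1_new = max(s1_new, 1e-4)
        s2_new = max(s2_new, 1e-4)
        change = max(abs(mu1_new - mu1), abs(mu2_new - mu2),
                     abs(s1_new - s1), abs(s2_new - s2), abs(mp_new - mp))
        mu1, mu2, s1, s2, mp = mu1_new, mu2_new, s1_new, s2_new, mp_new
        if not np.isfinite([mu1, mu2, s1, s2]).all():
            raise EmDivergenceError("region mixture EM diverged")
        if change < eps:
            break
    if mu1 < mu2:
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
        mp = 1.0 - mp
    return RegionMixtureFit(mu1, mu2, s1, s2, mp, n, trace)


def pooled_region_fit(xy: np.ndarray) -> RegionMixtureFit:
    """Low-confidence fallback when a segment has too few heterozygotes.

    Uses the per-SNP (max, min) intensity split over *all* SNPs of the
    segment, which is exact for LOH-like regions where every genotype
    class concentrates the signal on a single allele.
    """
    xy = np.asarray(xy, dtype=float)
    hi = xy.max(axis=1)
    lo = xy.min(axis=1)
    return RegionMixtureFit(float(hi.mean()), float(lo.mean()),
                            float(max(hi.std(ddof=1), 1e-4)),
                            float(max(lo.std(ddof=1), 1e-4)),
                            0.5, len(xy), [], confidence="low")


def estimate_baseline(values: np.ndarray) -> BaselineSummary:
    """Per-allele baseline level from pooled normal-segment het intensities."""
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise BaselineError(
            "no (or too few) normal segments to estimate a baseline; "
            "supply a user baseline level")
    return BaselineSummary(float(values.mean()),
                           float(values.std(ddof=1)), len(values))


def _welch(delta, s1, n1, s0, n0):
    """Welch t statistic, df and two-sided p for a mean difference."""
    v1 = s1 ** 2 / n1
    v0 = s0 ** 2 / n0
    se = np.sqrt(v1 + v0)
    t = delta / se
    df = (v1 + v0) ** 2 / (v1 ** 2 / (n1 - 1) + v0 ** 2 / (n0 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def test_region(fit: RegionMixtureFit, baseline: BaselineSummary,
                n_segments_tested: int, alpha: float = 0.05):
    """Welch t-tests of major, minor and total against the baseline.

    Returns (tests, alpha_bonf) where alpha_bonf = alpha / (3 *
    n_segments_tested), three tests being performed per segment.
    """
    n1 = max(fit.n_het, 2)
    t_maj, p_maj = _welch(fit.mu_major - baseline.mu, fit.sigma_major, n1,
                          baseline.sigma, baseline.n)
    t_min, p_min = _welch(fit.mu_minor - baseline.mu, fit.sigma_minor, n1,
                          baseline.sigma, baseline.n)
    s_tot = np.sqrt(fit.sigma_major ** 2 + fit.sigma_minor ** 2)
    t_tot, p_tot = _welch(fit.mu_major + fit.mu_minor - 2 * baseline.mu,
                          s_tot, n1, 2 * baseline.sigma, baseline.n)
    tests = SegmentTests(t_maj, t_min, t_tot, p_maj, p_min, p_tot,
                         fit.mu_major - baseline.mu,
                         fit.mu_minor - baseline.mu,
                         fit.mu_major + fit.mu_minor - 2 * baseline.mu)
    alpha_bonf = alpha / (3.0 * max(n_segments_tested, 1))
    return tests, alpha_bonf


def classify_segment(tests: SegmentTests, alpha_bonf: float,
                     min_effect: float = 0.0) -> str:
    """Six-way aberration call from the three Bonferroni-corrected tests.

    A deviation counts only when it is both statistically significant at
    the Bonferroni level and at least ``min_effect`` copy-number units in
    magnitude.  Swap normalization (major >= minor) makes the
    major-down/minor-up cell impossible; a significant minor-up with a
    non-significant major means the relabeled chromosome changed, i.e. a
    single-chromosome gain.
    """
    maj_up = tests.p_major < alpha_bonf and tests.t_major > 0 \
        and tests.e_major >= min_effect
    maj_dn = tests.p_major < alpha_bonf and tests.t_major < 0 \
        and tests.e_major <= -min_effect
    min_up = tests.p_minor < alpha_bonf and tests.t_minor > 0 \
        and tests.e_minor >= min_effect
    min_dn = tests.p_minor < alpha_bonf and tests.t_minor < 0 \
        and tests.e_minor <= -min_effect
    tot_sig = tests.p_total < alpha_bonf and abs(tests.e_total) >= min_effect
    if maj_up and min_up:
        return "gain/gain"
    if maj_up and min_dn:
        return "unbalanced gain/loss" if tot_sig else "balanced gain/loss"
    if maj_up:
        return "gain/normal"
    if min_up:
        return "gain/normal"
    if maj_dn and min_dn:
        return "loss/loss"
    if min_dn:
        return "normal/loss"
    if maj_dn:
        return "normal/loss"
    return "normal"


def inherited_loh_probability(het_rates: np.ndarray) -> float:
    """Chance that the inherited genotypes are homozygous at every SNP.

    Independence approximation: product of (1 - h_i) over the segment.
    Long LOH regions give vanishing probability and are therefore
    credible somatic events; short ones may be inherited runs of
    homozygosity.
    """
    h = np.asarray(het_rates, dtype=float)
    with np.errstate(divide="ignore"):
        return float(np.exp(np.sum(np.log1p(-np.minimum(h, 1.0)))))


def classify_segments(track: AlleleSignalTrack, genotypes,
                      theta_posterior, changepoints, priors: GenotypePrior,
                      alpha: float = 0.05, min_effect: float = 0.1,
                      loh_flag_threshold: float = 1e-3,
                      baseline: BaselineSummary | None = None,
                      ) -> list[SegmentCall]:
    """Characterize every segment of a hard segmentation.

    The baseline per-allele level pools the heterozygous SNPs of all
    segments whose posterior is predominantly at the normal state; if no
    segment qualifies a user-supplied ``baseline`` is required.
    """
    g = np.asarray(genotypes)
    u = track.u
    n = len(track)
    segs = changepoints.segments(n)
    theta = theta_posterior.theta_hat
    het = (g == AB) | (g == BA)

    if baseline is None:
        # preliminary normal: posterior means sit at the diploid baseline
        dev = np.linalg.norm(theta - 1.0, axis=1)
        normal_like = [seg for seg in segs
                       if np.median(dev[seg[0]:seg[1] + 1]) < 0.15]
        vals = []
        for a, b in normal_like:
            sel = het[a:b + 1]
            vals.append(u[a:b + 1][sel].ravel())
        pooled = np.concatenate(vals) if vals else np.empty(0)
        baseline = estimate_baseline(pooled)

    # reference heterozygote fraction for the het-deficit check, taken
    # from the normal-like segments (or the whole track if none)
    if baseline is None and normal_like:
        ref_het = float(np.mean([het[a:b + 1].mean()
                                 for a, b in normal_like]))
    else:
        ref_het = float(het.mean())

    calls = []
    nseg = len(segs)
    for a, b in segs:
        sel = het[a:b + 1]
        het_xy = u[a:b + 1][sel]
        # the het EM needs a credible heterozygote set: inside complete
        # LOH the few SNPs still called het are noise artifacts, so a
        # strong het deficit routes to the pooled (max, min) fallback,
        # which is exact when the signal concentrates on one allele
        if len(het_xy) >= 10 and sel.mean() >= 0.6 * ref_het:
            fit = fit_region_mixture(het_xy)
        else:
            fit = pooled_region_fit(u[a:b + 1])
        tests, alpha_bonf = test_region(fit, baseline, nseg, alpha)
        label = classify_segment(tests, alpha_bonf, min_effect)
        loh_prob = None
        flagged = False
        if label != "normal" and fit.mu_minor < 0.25:
            h = priors.het_rate[a:b + 1]
            loh_prob = inherited_loh_probability(h)
            flagged = loh_prob > loh_flag_threshold
        calls.append(SegmentCall(
            chrom=track.chrom, start_pos=int(track.pos[a]),
            end_pos=int(track.pos[b]), start_index=a, end_index=b,
            fit=fit, tests=tests, label=label,
            inherited_loh_prob=loh_prob, loh_flagged=flagged))
    return calls


_BED_COLORS = {
    "gain/gain": "200,0,0", "gain/normal": "255,80,80",
    "balanced gain/loss": "128,0,128", "unbalanced gain/loss": "180,0,180",
    "normal/loss": "80,80,255", "loss/loss": "0,0,200",
    "normal": "160,160,160",
}


def write_segments_bed(calls, path) -> None:
    """BED6+ (0-based half-open) with label names and per-type colors."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start_pos - 1}\t{c.end_pos}\t"
                     f"{c.label.replace(' ', '_')}\t0\t.\t"
                     f"{c.start_pos - 1}\t{c.end_pos}\t"
                     f"{_BED_COLORS[c.label]}\n")
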