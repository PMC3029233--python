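"""Synthetic tumor-dilution chromosome generator.

Emulates an Illumina-style ~42,000-SNP diploid chromosome: inherited
genotype configurations drawn from population heterozygosity priors,
imposed (major, minor) copy-number segments, tumor/normal mixing at a
stated contamination fraction, and per-genotype-class bivariate Gaussian
noise.  Every downstream module is testable against the emitted ground
truth without any external download.

Defaults represent the benchmark conditions used throughout the test
suite: heterozygosity 0.3, noise standard deviation 0.15 per coordinate
for heterozygous and 0.18 for homozygous classes (an Illumina 550k-like
noise scale), and a linear signal response over copy numbers 0-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .hmm import ASSIGNMENT
from .io import AB, BA, AlleleSignalTrack, GenotypePrior

DEFAULT_N_SNPS = 42_000
DEFAULT_HET_RATE = 0.3
DEFAULT_SIGMA_HET = 0.15
DEFAULT_SIGMA_HOM = 0.18


@dataclass(frozen=True)
class AberrationSpec:
    """One imposed copy-number region, SNP indices 1-based inclusive."""

    start_index: int
    end_index: int
    major: float
    minor: float

    def __post_init__(self):
        if not (0 <= self.minor <= self.major):
            raise ValueError("need 0 <= minor <= major")
        if self.end_index < self.start_index:
            raise ValueError("end_index before start_index")

    @property
    def label(self) -> str:
        return aberration_label(self.major, self.minor)

    def slice(self) -> slice:
        return slice(self.start_index - 1, self.end_index)


def aberration_label(major: float, minor: float,
                     baseline: float = 1.0, total: float = 2.0) -> str:
    """Generating six-way label of a (major, minor) pair."""
    up = major > baseline
    dn_minor = minor < baseline
    up_minor = minor > baseline
    dn = major < baseline
    if up and up_minor:
        return "gain/gain"
    if up and dn_minor:
        return ("balanced gain/loss" if np.isclose(major + minor, total)
                else "unbalanced gain/loss")
    if up:
        return "gain/normal"
    if dn and dn_minor:
        return "loss/loss"
    if dn_minor:
        return "normal/loss"
    return "normal"


def table2_specs() -> list[AberrationSpec]:
    """The six-region benchmark layout (one region per aberration type)."""
    return [
        AberrationSpec(2000, 5000, 3, 2),      # gain/gain
        AberrationSpec(9000, 12000, 2, 1),     # gain/normal
        AberrationSpec(16000, 19000, 2, 0),    # balanced gain/loss
        AberrationSpec(23000, 26000, 3, 0),    # unbalanced gain/loss
        AberrationSpec(30000, 33000, 1, 0),    # normal/loss
        AberrationSpec(37000, 40000, 0, 0),    # loss/loss
    ]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated track."""

    theta: np.ndarray         # (n, 2) diluted parent copy numbers
    genotypes: np.ndarray     # (n,) codes 0..3 (inherited configurations)
    specs: list               # the imposed AberrationSpec list
    contamination: float
    orientations: np.ndarray  # per-region: 0 = (major, minor) on parent 1

    def region_label(self, k: int) -> str:
        return self.specs[k].label

    def aberrant_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.theta), dtype=bool)
        for sp in self.specs:
            mask[sp.slice()] = True
        return mask

    def to_frame(self):
        import pandas as pd
        labels = np.full(len(self.theta), "normal", dtype=object)
        for sp in self.specs:
            labels[sp.slice()] = sp.label
        from .model import GENOTYPE_LABELS
        return pd.DataFrame({
            "index": np.arange(len(self.theta)),
            "theta1": self.theta[:, 0], "theta2": self.theta[:, 1],
            "genotype": GENOTYPE_LABELS[self.genotypes],
            "region_label": labels,
        })


def _default_sigmas():
    het = np.diag([DEFAULT_SIGMA_HET ** 2] * 2)
    hom = np.diag([DEFAULT_SIGMA_HOM ** 2] * 2)
    return np.stack([hom, het, het, hom, het])


def simulate_chromosome(n_snps: int = DEFAULT_N_SNPS,
                        specs: Sequence[AberrationSpec] | None = None,
                        contamination: float = 0.0,
                        noise: np.ndarray | None = None,
                        het_rate: float = DEFAULT_HET_RATE,
                        seed: int = 0,
                        chrom: str = "1",
                        ) -> tuple[AlleleSignalTrack, SimTruth]:
    """Simulate one chromosome with imposed aberrations and dilution.

    The tumor parent-specific copy numbers are (1, 1) outside the
    ``specs`` regions and (major, minor) inside, with a random parent
    orientation per region; mixing ``contamination`` parts normal cells
    gives theta = c*(1,1) + (1-c)*theta_tumor.  The observation is
    A(g) theta plus genotype-class Gaussian noise.  For a fixed seed the
    genotype, orientation and noise draws are identical across
    contamination levels, enabling paired dilution series.
    """
    if not 0.0 <= contamination <= 1.0:
        raise ValueError(f"contamination must be in [0, 1], "
                         f"got {contamination}")
    if specs is None:
        specs = table2_specs()
    specs = sorted(specs, key=lambda s: s.start_index)
    for a, b in zip(specs, specs[1:]):
        if b.start_index <= a.end_index:
            raise ValueError("aberration regions overlap")
    if specs and specs[-1].end_index > n_snps:
        raise ValueError("aberration region exceeds n_snps")
    if noise is None:
        noise = _default_sigmas()

    rng = np.random.default_rng(seed)
    probs = [(1 - het_rate) / 2, het_rate / 2, het_rate / 2,
             (1 - het_rate) / 2]
    g = rng.choice(4, size=n_snps, p=probs)
    orientations = rng.integers(0, 2, size=len(specs))
    chol = np.linalg.cholesky(noise)
    eps = rng.standard_normal((n_snps, 2))
    eps = np.einsum("tij,tj->ti", chol[g], eps)

    theta_tumor = np.ones((n_snps, 2))
    for sp, flip in zip(specs, orientations):
        pair = (sp.minor, sp.major) if flip else (sp.major, sp.minor)
        theta_tumor[sp.slice()] = pair
    c = float(contamination)
    theta = c * 1.0 + (1.0 - c) * theta_tumor

    u = np.einsum("tij,tj->ti", ASSIGNMENT[g], theta) + eps
    snp_id = np.array([f"snp{i + 1}" for i in range(n_snps)], dtype=object)
    track = AlleleSignalTrack(snp_id, chrom, np.arange(1, n_snps + 1),
                              u[:, 0], u[:, 1], platform="raw_xy")
    truth = SimTruth(theta, g, list(specs), c, orientations)
    return track, truth


def simulation_priors(n_snps: int = DEFAULT_N_SNPS,
                      het_rate: float = DEFAULT_HET_RATE) -> GenotypePrior:
    """The population genotype priors matching the generator."""
    return GenotypePrior.from_het_rate(np.full(n_snps, het_rate))


def dilution_series(n_snps: int = DEFAULT_N_SNPS,
                    specs: Sequence[AberrationSpec] | None = None,
                    levels: Sequence[float] = (),
                    seeds: Sequence[int] = (0,),
                    **kwargs) -> Iterator[tuple]:
    """Yield (track, truth, contamination, seed) over a dilution grid.

    For a given seed the genotype and noise draws are identical at every
    contamination level, so sensitivity curves are paired.
    """
    for c in levels:
        for seed in seeds:
            track, truth = simulate_chromosome(
                n_snps=n_snps, specs=specs, contamination=c,
                seed=seed, **kwargs)
            yield track, truth, c, seed
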