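"""Reading, writing and transforming allele-specific SNP-array signals.

The model operates on bivariate per-SNP allele intensities ``(x, y)`` — the
normalized raw copy numbers of the arbitrarily labelled A and B alleles.
Illumina-style platforms instead report ``logR`` (log2 total intensity
relative to the diploid reference) and ``BAF`` (the B-allele frequency,
a scaled arc-tangent of the B/A intensity ratio).  This module converts
between the two representations and loads per-SNP tables and genotype
priors from disk.

Conventions
-----------
* Total intensity scale: ``R = 2 * 2**logR`` so that a normal diploid SNP
  (logR = 0) has R = 2 and a per-parent baseline copy number of 1.  Copy
  numbers are therefore directly readable (a single-copy gain of one
  chromosome reads as 2).
* BAF dialect: by default BAF is the Illumina arc-tangent quantity
  ``(2/pi) * arctan(y/x)``; ``baf_dialect="ratio"`` selects the naive
  ratio ``y / (x + y)`` instead.
* Positions are 1-based physical coordinates and must be unique per
  chromosome; tracks are sorted on load.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("AA", "AB", "BA", "BB", "NP")
#: integer codes used throughout the package
AA, AB, BA, BB, NP = range(5)


class FormatError(ValueError):
    """Input file does not conform to the expected table dialect."""


class ValidationError(ValueError):
    """Input file parses but violates a content invariant."""


@dataclass
class AlleleSignalTrack:
    """Ordered per-SNP bivariate allele intensities for one chromosome.

    Parameters
    ----------
    snp_id : array of str
    chrom : str
        Single chromosome name shared by all SNPs.
    pos : array of int
        1-based physical coordinates, strictly increasing.
    x, y : array of float
        Normalized A- and B-allele intensities (the observed signal
        ``u_t``).  Values may be slightly negative for raw platform
        output; reading from disk clamps at 0 by default.
    platform : str
        ``"raw_xy"`` or ``"illumina_logr_baf"`` — provenance of the data.
    """

    snp_id: np.ndarray
    chrom: str
    pos: np.ndarray
    x: np.ndarray
    y: np.ndarray
    platform: str = "raw_xy"

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.x = np.ascontiguousarray(self.x, dtype=np.float64)
        self.y = np.ascontiguousarray(self.y, dtype=np.float64)
        n = len(self.pos)
        if not (len(self.x) == len(self.y) == len(self.snp_id) == n):
            raise ValidationError("track arrays have unequal lengths")
        if n < 2:
            raise ValidationError("a track needs at least 2 SNPs")
        if np.any(np.diff(self.pos) <= 0):
            raise ValidationError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def u(self) -> np.ndarray:
        """(n, 2) array of observations."""
        return np.column_stack([self.x, self.y])

    def reversed(self) -> "AlleleSignalTrack":
        """Track with SNP order (and coordinates) reversed."""
        pos = self.pos[-1] + 1 - self.pos[::-1]
        return AlleleSignalTrack(self.snp_id[::-1], self.chrom, pos,
                                 self.x[::-1], self.y[::-1], self.platform)

    def swapped_alleles(self) -> "AlleleSignalTrack":
        """Track with the arbitrary A/B allele labels exchanged."""
        return AlleleSignalTrack(self.snp_id, self.chrom, self.pos,
                                 self.y.copy(), self.x.copy(), self.platform)

    def to_frame(self, representation: str = "xy") -> pd.DataFrame:
        df = pd.DataFrame({"snp_id": self.snp_id, "chrom": self.chrom,
                           "pos": self.pos})
        if representation == "xy":
            df["x"], df["y"] = self.x, self.y
        elif representation == "logr_baf":
            logr, baf = xy_to_logr_baf(self.x, self.y)
            df["logR"], df["BAF"] = logr, baf
        else:
            raise ValueError(f"unknown representation {representation!r}")
        return df

    def write(self, path, representation: str = "xy") -> None:
        self.to_frame(representation).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypePrior:
    """Per-SNP multinomial prior over inherited genotype configurations.

    ``probs`` is an (n, 4) array of (pi_AA, pi_AB, pi_BA, pi_BB), each row
    summing to 1; ``non_polymorphic`` marks copy-number-only markers whose
    genotype is pinned to the NP class so that only total intensity
    informs the segmentation.
    """

    probs: np.ndarray
    non_polymorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValidationError("prior must be (n, 4)")
        if self.non_polymorphic is None:
            self.non_polymorphic = np.zeros(len(self.probs), dtype=bool)
        self.non_polymorphic = np.asarray(self.non_polymorphic, dtype=bool)
        rows = self.probs.sum(axis=1)
        ok = np.isclose(rows, 1.0, atol=1e-9) | self.non_polymorphic
        if not np.all(ok):
            raise ValidationError("prior rows must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def het_rate(self) -> np.ndarray:
        """Per-SNP heterozygosity pi_AB + pi_BA (0 for NP markers)."""
        h = self.probs[:, 1] + self.probs[:, 2]
        h = np.where(self.non_polymorphic, 0.0, h)
        return h

    @classmethod
    def uniform(cls, n: int) -> "GenotypePrior":
        return cls(np.full((n, 4), 0.25))

    @classmethod
    def from_het_rate(cls, h) -> "GenotypePrior":
        h = np.asarray(h, dtype=np.float64)
        if np.any((h < 0) | (h > 1)):
            raise ValidationError("heterozygosity rates must lie in [0, 1]")
        probs = np.column_stack([(1 - h) / 2, h / 2, h / 2, (1 - h) / 2])
        return cls(probs)

    def swapped_alleles(self) -> "GenotypePrior":
        """Prior under exchange of the A/B allele labels (AA<->BB, AB<->BA)."""
        return GenotypePrior(self.probs[:, [3, 2, 1, 0]].copy(),
                             self.non_polymorphic.copy())


# ---------------------------------------------------------------------------
# logR/BAF <-> (x, y) transforms
# ---------------------------------------------------------------------------

def logr_baf_to_xy(logr, baf, baf_dialect: str = "arctan"):
    """Convert (logR, BAF) to allele intensities (x, y).

    Total intensity is ``R = 2 * 2**logR``; the split between x and y is
    set by BAF under the chosen dialect.  Vectorized; scalars in,
    scalars out.
    """
    logr = np.asarray(logr, dtype=np.float64)
    baf = np.asarray(baf, dtype=np.float64)
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF must lie in [0, 1]")
    R = 2.0 * np.exp2(logr)
    if baf_dialect == "arctan":
        # y/x = tan(baf * pi/2); handle both boundaries without overflow
        t = np.tan(baf * (np.pi / 2.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(baf >= 1.0, 0.0, R / (1.0 + t))
    elif baf_dialect == "ratio":
        x = R * (1.0 - baf)
    else:
        raise ValueError(f"unknown baf_dialect {baf_dialect!r}")
    y = R - x
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def xy_to_logr_baf(x, y, baf_dialect: str = "arctan"):
    """Inverse of :func:`logr_baf_to_xy` (requires x + y > 0)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    R = x + y
    if np.any(R <= 0):
        raise ValueError("x + y must be positive to define logR")
    logr = np.log2(R / 2.0)
    if baf_dialect == "arctan":
        baf = (2.0 / np.pi) * np.arctan2(y, x)
    elif baf_dialect == "ratio":
        baf = y / R
    else:
        raise ValueError(f"unknown baf_dialect {baf_dialect!r}")
    if logr.ndim == 0:
        return float(logr), float(baf)
    return logr, baf


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_snp_table(path, format: str | None = None,
                   baf_dialect: str = "arctan",
                   clamp_negative: bool = True) -> dict[str, AlleleSignalTrack]:
    """Read a per-SNP TSV into one :class:`AlleleSignalTrack` per chromosome.

    The file must have a header with columns ``snp_id``, ``chrom``, ``pos``
    plus either ``x``/``y`` (format ``"raw_xy"``) or ``logR``/``BAF``
    (format ``"illumina_logr_baf"``).  ``format=None`` autodetects from the
    header.  Rows with non-finite signal values are dropped (counted and
    logged); duplicated (chrom, pos) pairs are a :class:`ValidationError`.

    Returns a dict keyed by chromosome name, each track sorted by position.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    cols = set(df.columns)
    if not {"snp_id", "chrom", "pos"} <= cols:
        raise FormatError(f"missing required columns in {path}: "
                          f"need snp_id, chrom, pos; got {sorted(cols)}")
    if format is None:
        if {"x", "y"} <= cols:
            format = "raw_xy"
        elif {"logR", "BAF"} <= cols:
            format = "illumina_logr_baf"
        else:
            raise FormatError("need either x/y or logR/BAF columns")
    if format == "raw_xy":
        sig_cols = ["x", "y"]
    elif format == "illumina_logr_baf":
        sig_cols = ["logR", "BAF"]
    else:
        raise FormatError(f"unknown format {format!r}")
    if not set(sig_cols) <= cols:
        raise FormatError(f"format {format!r} requires columns {sig_cols}")

    bad = ~np.isfinite(df[sig_cols].to_numpy(dtype=np.float64)).all(axis=1)
    if format == "illumina_logr_baf":
        bad |= (df["BAF"] < 0) | (df["BAF"] > 1)
    if bad.any():
        logger.warning("dropped %d rows with non-finite or out-of-range "
                       "signal values (lines %s)", int(bad.sum()),
                       [int(i) + 2 for i in np.flatnonzero(bad)[:10]])
        df = df[~bad]

    if df.duplicated(subset=["chrom", "pos"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise ValidationError(
            f"duplicated (chrom, pos) = ({dup['chrom']}, {dup['pos']})")

    tracks: dict[str, AlleleSignalTrack] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        if format == "illumina_logr_baf":
            x, y = logr_baf_to_xy(sub["logR"].to_numpy(),
                                  sub["BAF"].to_numpy(), baf_dialect)
        else:
            x = sub["x"].to_numpy(dtype=np.float64)
            y = sub["y"].to_numpy(dtype=np.float64)
        if clamp_negative:
            n_neg = int((x < 0).sum() + (y < 0).sum())
            if n_neg:
                logger.info("clamped %d negative intensities to 0 on %s",
                            n_neg, chrom)
            x = np.maximum(x, 0.0)
            y = np.maximum(y, 0.0)
        tracks[str(chrom)] = AlleleSignalTrack(
            sub["snp_id"].to_numpy(), str(chrom),
            sub["pos"].to_numpy(), x, y, platform=format)
    return tracks


def load_genotype_priors(path, track: AlleleSignalTrack) -> GenotypePrior:
    """Build per-SNP genotype priors from a heterozygosity table.

    ``path`` is a TSV with columns ``snp_id`` and ``het_rate``; SNPs of the
    track present in the file with heterozygosity h receive
    ((1-h)/2, h/2, h/2, (1-h)/2), absent SNPs the uniform prior.  ``path``
    may be None, in which case every SNP gets the uniform prior (which
    works reasonably well because the genotype configurations are only
    surrogate information for the copy-number posterior).
    """
    n = len(track)
    if path is None:
        return GenotypePrior.uniform(n)
    with _open_text(path) as fh:
        tab = pd.read_csv(fh, sep="\t")
    if not {"snp_id", "het_rate"} <= set(tab.columns):
        raise FormatError("prior file needs columns snp_id, het_rate")
    h = tab.set_index("snp_id")["het_rate"]
    if ((h < 0) | (h > 1)).any():
        raise ValidationError("het_rate outside [0, 1]")
    rates = pd.Series(0.5, index=track.snp_id)  # uniform <=> h = 0.5
    common = rates.index.intersection(h.index)
    rates.loc[common] = h.loc[common]
    return GenotypePrior.from_het_rate(rates.to_numpy(dtype=np.float64))
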