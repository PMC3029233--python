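"""Run configuration: every pipeline tunable with its default.

Serializes to and from a flat ``key = value`` text file; unknown keys
are rejected so that typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class RunConfig:
    """Tunable parameters of the segmentation pipeline.

    tol : stopping threshold on the mean per-SNP change of theta_hat
        between E-steps (copy-number units).
    max_iter : cap on E/M alternations.
    d_threshold : one-step Euclidean distance above which a boundary is a
        changepoint candidate (copy-number units); deliberately low, with
        false positives removed by the rank-sum merge.
    min_sep : minimum number of SNPs between changepoints.
    wilcoxon_alpha : p-value threshold of the rank-sum merge tests.
    bcmix_M, bcmix_K : BCMIX pruning sizes (components kept / most recent
        change-times always kept).
    seed : seed for the genotype initialization.
    baf_dialect : meaning of the BAF column on disk (arctan | ratio).
    alpha : family-wise level of the segment t-tests (Bonferroni over
        3 tests per segment).
    min_effect : smallest copy-number deviation treated as a real change;
        with thousands of SNPs per segment the t-tests resolve shifts far
        below the scale of any genuine aberration, so statistical
        significance alone would call tiny estimation biases.
    loh_flag_threshold : chance-homozygosity probability above which an
        LOH-like segment is flagged possible-inherited-LOH.
    """

    tol: float = 1e-4
    max_iter: int = 20
    d_threshold: float = 0.1
    min_sep: int = 20
    wilcoxon_alpha: float = 1e-4
    bcmix_M: int = 20
    bcmix_K: int = 10
    seed: int = 0
    baf_dialect: str = "arctan"
    alpha: float = 0.05
    min_effect: float = 0.1
    loh_flag_threshold: float = 1e-3

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, val = (part.strip() for part in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = casts[types[key]](val)
        return cls(**kwargs)
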