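"""Scoring called segments against simulated truth.

Conventions: a true aberrant region counts as *detected* when at least
half of its SNPs are covered by non-normal calls; it is *type-correct*
when some called segment with >= 50% reciprocal overlap carries exactly
the generating label.  Overall specificity is the fraction of SNPs
outside every true aberration that are not called non-normal; the
type-correct variant additionally counts wrongly-typed calls on true
regions as errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_SCAN_LEVELS = tuple(range(0, 100, 5))


@dataclass
class EvalMetrics:
    sensitivity: float
    type_correct_sensitivity: float
    specificity: float
    type_correct_specificity: float
    per_region: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sensitivity": self.sensitivity,
            "type_correct_sensitivity": self.type_correct_sensitivity,
            "specificity": self.specificity,
            "type_correct_specificity": self.type_correct_specificity,
        }])


def _call_table(calls) -> pd.DataFrame:
    """Normalize a list of SegmentCall or a segments DataFrame."""
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
        if "start_index" not in df:
            df["start_index"] = df["start"] - 1
            df["end_index"] = df["end"] - 1
        return df[["start_index", "end_index", "label"]]
    return pd.DataFrame([{"start_index": c.start_index,
                          "end_index": c.end_index,
                          "label": c.label} for c in calls])


def region_type_correct(calls, start_index: int, end_index: int,
                        label: str, min_overlap: float = 0.5) -> bool:
    """Is a true region matched by a correctly-typed call?

    Requires >= ``min_overlap`` reciprocal overlap (of both the true
    region and the calling segment) and an exact label match.
    """
    df = _call_table(calls)
    tlen = end_index - start_index + 1
    for _, row in df.iterrows():
        ov = (min(end_index, row.end_index)
              - max(start_index, row.start_index) + 1)
        clen = row.end_index - row.start_index + 1
        if ov >= min_overlap * tlen and ov >= min_overlap * clen \
                and row.label == label:
            return True
    return False


def evaluate_calls(calls, truth_regions, n_snps: int,
                   min_overlap: float = 0.5) -> EvalMetrics:
    """Region-level sensitivity and SNP-level specificity.

    ``truth_regions`` is an iterable of (start_index, end_index, label)
    with 0-based inclusive indices, or AberrationSpec-like objects with
    1-based ``start_index``/``end_index`` and a ``label`` attribute.
    """
    regions = []
    for tr in truth_regions:
        if hasattr(tr, "slice"):
            regions.append((tr.start_index - 1, tr.end_index - 1, tr.label))
        else:
            regions.append(tuple(tr))

    df = _call_table(calls)
    called = np.zeros(n_snps, dtype=bool)
    wrong_type = np.zeros(n_snps, dtype=bool)
    for _, row in df.iterrows():
        if row.label != "normal":
            called[row.start_index:row.end_index + 1] = True

    truth_mask = np.zeros(n_snps, dtype=bool)
    rows = []
    for a, b, lab in regions:
        truth_mask[a:b + 1] = True
        cov = called[a:b + 1].mean() if b >= a else 0.0
        detected = cov >= min_overlap
        correct = region_type_correct(df, a, b, lab, min_overlap)
        rows.append({"start_index": a, "end_index": b, "label": lab,
                     "coverage": cov, "detected": detected,
                     "type_correct": correct})
        if detected and not correct:
            wrong_type[a:b + 1] = True
    per_region = pd.DataFrame(rows)

    outside = ~truth_mask
    spec = float((~called[outside]).mean()) if outside.any() else 1.0
    fp = called & outside
    fp_or_wrong = fp.copy()
    fp_or_wrong |= wrong_type
    denom = int(outside.sum() + truth_mask.sum())
    type_spec = 1.0 - float(fp_or_wrong.sum()) / denom if denom else 1.0

    sens = float(per_region["detected"].mean()) if len(per_region) else 1.0
    tsens = float(per_region["type_correct"].mean()) if len(per_region) else 1.0
    return EvalMetrics(sens, tsens, spec, type_spec, per_region)


def dilution_type_thresholds(levels=DEFAULT_SCAN_LEVELS, seeds=(0, 1, 2),
                             n_snps=None, het_rate=None, config=None,
                             progress=False):
    """Largest tolerable contamination per aberration type.

    Re-runs the full segment-and-classify pipeline on the six-region
    benchmark chromosome over a grid of contamination percentages with
    several seeded replicates, and reports, for each imposed region, the
    largest level at which the region receives its exact generating
    label (majority of replicates), mirroring a tumor dilution
    titration.

    Returns (thresholds, detail) where ``thresholds`` maps region label
    -> largest correct percentage (or -1 if never correct) and
    ``detail`` is a tidy DataFrame of per-run outcomes.
    """
    from .config import RunConfig
    from .model import PscnModel
    from .simulate import (DEFAULT_HET_RATE, DEFAULT_N_SNPS,
                           simulate_chromosome, simulation_priors,
                           table2_specs)

    n_snps = n_snps or DEFAULT_N_SNPS
    het_rate = het_rate or DEFAULT_HET_RATE
    config = config or RunConfig()
    specs = table2_specs()
    priors = simulation_priors(n_snps, het_rate)
    rows = []
    for level in levels:
        for seed in seeds:
            track, truth = simulate_chromosome(
                n_snps=n_snps, specs=specs, contamination=level / 100.0,
                het_rate=het_rate, seed=seed)
            res = PscnModel(track, priors=priors, config=config).fit(
                seed=seed)
            for sp in specs:
                ok = region_type_correct(
                    res.segments, sp.start_index - 1, sp.end_index - 1,
                    sp.label)
                rows.append({"level": level, "seed": seed,
                             "label": sp.label, "correct": ok})
            if progress:
                got = [r["label"] for r in rows[-len(specs):]
                       if r["correct"]]
                print(f"  c={level:>2}% seed={seed}: "
                      f"{len(got)}/6 correct", flush=True)
    detail = pd.DataFrame(rows)
    need = (len(seeds) // 2) + 1
    thresholds = {}
    for label, sub in detail.groupby("label"):
        per_level = sub.groupby("level")["correct"].sum()
        ok_levels = per_level[per_level >= need].index
        thresholds[label] = int(max(ok_levels)) if len(ok_levels) else -1
    return thresholds, detail
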