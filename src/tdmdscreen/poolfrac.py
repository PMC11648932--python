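"""Fraction of the cellular miRNA pool degraded through the ligase.

Per replicate pair (one wild-type and one mutant library of the same stage
and replicate number), raw miRNA counts are summed separately over the
sensitive and non-sensitive sets.  The wild-type sums are scaled so that
the non-sensitive totals match between genotypes — absolute comparison is
then possible because non-sensitive miRNAs are assumed unchanged — and the
surplus of sensitive counts in the mutant over the scaled wild type,
divided by the mutant's total miRNA counts, estimates the fraction of
miRNA molecules that would have been degraded:

    k        = sum_mut(non-sensitive) / sum_wt(non-sensitive)
    surplus  = sum_mut(sensitive) - k * sum_wt(sensitive)
    fraction = surplus / sum_mut(all miRNAs)

Negative surpluses are reported as computed, not clipped: the estimator is
pure arithmetic and a negative value is a diagnostic, not an error.  The
sensitive set used is the stage-specific call set.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import MUTANT, WT, CountMatrix

logger = logging.getLogger(__name__)


def pool_fraction_pair(
    wt_counts: pd.Series, mut_counts: pd.Series, sensitive: set[str]
) -> dict:
    """The arithmetic on one replicate pair of raw count vectors."""
    features = wt_counts.index
    sens_mask = features.isin(sensitive)
    wt_ns = float(wt_counts[~sens_mask].sum())
    mut_ns = float(mut_counts[~sens_mask].sum())
    if wt_ns == 0:
        raise ValueError("wild-type non-sensitive count sum is zero; cannot scale")
    if not sensitive:
        logger.info("empty sensitive set: degraded fraction is 0 by definition")
        return {"scale": mut_ns / wt_ns, "surplus": 0.0, "fraction": 0.0}
    k = mut_ns / wt_ns
    surplus = float(mut_counts[sens_mask].sum()) - k * float(wt_counts[sens_mask].sum())
    fraction = surplus / float(mut_counts.sum())
    return {"scale": k, "surplus": surplus, "fraction": fraction}


def degraded_fraction(
    counts: CountMatrix, sensitive: set[str], stage: str | None = None
) -> pd.DataFrame:
    """Per-replicate degraded fractions for one stage, plus the replicate mean.

    Replicates are paired by replicate number within the stage.  Returns a
    frame with one row per replicate and a final ``mean`` row.
    """
    stages = [stage] if stage is not None else counts.stages
    rows = []
    for st in stages:
        wt_libs = counts.libraries(genotype=WT, stage=st)
        mut_libs = counts.libraries(genotype=MUTANT, stage=st)
        wt_by_rep = {counts.meta.loc[lib, "replicate"]: lib for lib in wt_libs}
        mut_by_rep = {counts.meta.loc[lib, "replicate"]: lib for lib in mut_libs}
        reps = sorted(set(wt_by_rep) & set(mut_by_rep))
        if not reps:
            raise ValueError(f"no paired replicates for stage {st!r}")
        fracs = []
        for rep in reps:
            res = pool_fraction_pair(
                counts.counts[wt_by_rep[rep]], counts.counts[mut_by_rep[rep]], sensitive
            )
            fracs.append(res["fraction"])
            rows.append({"stage": st, "replicate": rep, **res})
        rows.append(
            {
                "stage": st,
                "replicate": "mean",
                "scale": float("nan"),
                "surplus": float("nan"),
                "fraction": sum(fracs) / len(fracs),
            }
        )
    return pd.DataFrame(rows)


def expected_fraction(truth, stage: str) -> float:
    """Planted expectation of the degraded fraction, from the truth table.

    With non-sensitive expectations equal across genotypes (fold 1), the
    expected surplus is sum_i base_i * (fold_i - 1) over sensitive guides
    and the expected mutant total is sum_i base_i * fold_i.
    """
    sens = set(truth.sensitive_guides(stage))
    base = truth.baseline
    fold = truth.fold[stage]
    surplus = sum(base[g] * (fold[g] - 1.0) for g in sens)
    mut_total = float((base * fold).sum())
    return surplus / mut_total
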