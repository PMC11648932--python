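"""Target-repression CDF analysis with 3'-UTR-length-matched controls.

Predicted targets of a miRNA family should shift left (down) in the
distribution of mutant-vs-wild-type mRNA fold changes if the surplus miRNA
represses them.  Because longer 3' UTRs are more repressible a priori,
control nontargets are sampled length-matched: for each target, a control
is drawn (randomly, with replacement, seeded) from the nontargets whose
longest annotated 3'-UTR length differs by at most a tolerance fraction of
the *target's* length — 10% for conserved-site targets, 15% for all
predicted targets.  Genes first pass a wild-type expression filter of 50
raw reads.  The target and control fold-change distributions are compared
with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLS = ("gene", "log2fc", "wt_reads", "utr_length")


def expression_filter_mrna(
    table: pd.DataFrame, min_reads: int = 50, inclusive: bool = True
) -> pd.DataFrame:
    """Keep genes whose wild-type raw read count reaches ``min_reads`` (inclusive)."""
    keep = table["wt_reads"] >= min_reads if inclusive else table["wt_reads"] > min_reads
    return table[keep].reset_index(drop=True)


@dataclass
class ControlSet:
    """Length-matched control genes: one frame row per (target, control) pair."""

    pairs: pd.DataFrame  # target, target_utr, control, control_utr
    tolerance: float
    seed: int
    dropped: list[str]  # targets with no eligible control

    def validate(self) -> None:
        rel = (self.pairs["control_utr"] - self.pairs["target_utr"]).abs() / self.pairs[
            "target_utr"
        ]
        if (rel > self.tolerance + 1e-12).any():
            raise AssertionError("control outside the length tolerance")


def select_controls(
    targets: pd.DataFrame,
    nontargets: pd.DataFrame,
    tolerance: float,
    seed: int,
    n_controls: int = 1,
) -> ControlSet:
    """Sample length-matched nontarget controls for each target gene.

    Eligibility: |len(control) - len(target)| <= tolerance * len(target)
    (inclusive).  Sampling is with replacement; targets with no eligible
    control are dropped and tallied.
    """
    if nontargets.empty:
        raise ValueError("no nontarget genes to sample controls from")
    rng = np.random.default_rng(seed)
    nt_len = nontargets["utr_length"].to_numpy(dtype=float)
    nt_gene = nontargets["gene"].to_numpy()
    rows, dropped = [], []
    for _, t in targets.iterrows():
        tlen = float(t["utr_length"])
        if tlen <= 0:
            dropped.append(t["gene"])
            continue
        eligible = np.flatnonzero(np.abs(nt_len - tlen) <= tolerance * tlen)
        if eligible.size == 0:
            dropped.append(t["gene"])
            continue
        picks = rng.choice(eligible, size=n_controls, replace=True)
        for idx in picks:
            rows.append(
                {
                    "target": t["gene"],
                    "target_utr": tlen,
                    "control": nt_gene[idx],
                    "control_utr": nt_len[idx],
                }
            )
    if not rows:
        raise ValueError("no target had an eligible length-matched control")
    cs = ControlSet(pd.DataFrame(rows), tolerance, seed, dropped)
    cs.validate()
    return cs


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample K-S: D = sup |ECDF_x - ECDF_y| with asymptotic two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(values)
    return xs, np.arange(1, xs.size + 1) / xs.size


def target_repression_report(
    table: pd.DataFrame,
    predicted_tol: float = 0.15,
    conserved_tol: float = 0.10,
    min_reads: int = 50,
    n_controls: int = 1,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-category (predicted, conserved) CDF data and K-S results.

    Returns, per category: target/control log2FC vectors and ECDF
    coordinates, the K-S D and p, sample sizes and dropped-target tally.
    """
    for col in REQUIRED_COLS:
        if col not in table.columns:
            raise ValueError(f"mRNA table missing column {col!r}")
    table = expression_filter_mrna(table, min_reads=min_reads)
    table = table[table["utr_length"] > 0]
    nontargets = table[~table["predicted_target"]]
    report: dict[str, dict] = {}
    for category, mask, tol in (
        ("predicted", table["predicted_target"], predicted_tol),
        ("conserved", table.get("conserved_target", table["predicted_target"]), conserved_tol),
    ):
        targets = table[mask]
        if targets.empty:
            continue
        cs = select_controls(targets, nontargets, tol, seed=seed, n_controls=n_controls)
        kept = targets[targets["gene"].isin(cs.pairs["target"])]
        t_fc = kept.set_index("gene")["log2fc"]
        target_vals = cs.pairs["target"].map(t_fc).to_numpy(dtype=float)
        c_fc = nontargets.set_index("gene")["log2fc"]
        control_vals = cs.pairs["control"].map(c_fc).to_numpy(dtype=float)
        d, p = ks_two_sample(target_vals, control_vals)
        tx, ty = _ecdf(target_vals)
        cx, cy = _ecdf(control_vals)
        report[category] = {
            "targets": target_vals,
            "controls": control_vals,
            "target_ecdf": (tx, ty),
            "control_ecdf": (cx, cy),
            "D": d,
            "pvalue": p,
            "n_targets": int(len(kept)),
            "n_pairs": int(len(cs.pairs)),
            "n_dropped": len(cs.dropped),
            "tolerance": tol,
        }
    return report


def summarize_mrna_de(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Up/down tallies of differentially expressed mRNAs at adjusted p < alpha."""
    if "padj" not in table.columns:
        raise ValueError("table lacks a padj column")
    sig = table[table["padj"] < alpha]
    return {
        "up": int((sig["log2fc"] > 0).sum()),
        "down": int((sig["log2fc"] < 0).sum()),
        "alpha": alpha,
    }


def plot_target_cdf(report: dict[str, dict], path) -> None:
    """Cumulative fold-change distributions, targets vs controls, per category."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(report), figsize=(4.5 * len(report), 3.5),
                             squeeze=False)
    for ax, (cat, res) in zip(axes[0], report.items()):
        ax.step(*res["target_ecdf"], where="post", color="crimson",
                label=f"targets (n={res['n_targets']})")
        ax.step(*res["control_ecdf"], where="post", color="steelblue",
                label=f"controls (n={res['n_pairs']})")
        ax.set_title(f"{cat}: D={res['D']:.3f}, p={res['pvalue']:.2g}")
        ax.set_xlabel("mRNA log2 fold change (mutant / WT)")
        ax.set_ylabel("cumulative fraction")
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
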