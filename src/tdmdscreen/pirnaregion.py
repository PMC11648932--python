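"""piRNA support filtering and genomic localisation of dysregulated blocks.

piRNAs (21U-RNAs) are transcribed from dense genomic clusters; a
transcriptional defect shows up as a *contiguous* block of coordinately
downregulated piRNAs rather than scattered hits.  After the support filter
(a piRNA must have at least one read in every library), a sliding-window
scan over the genome flags windows holding enough tested piRNAs whose
median log2 fold change falls at or below a threshold, and merges
overlapping flagged windows into maximal intervals.  The scan works on
fold changes rather than adjusted p-values, since coordinate downregulation
is visible well below per-feature significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(records: pd.DataFrame, path) -> None:
    """Write piRNA records as 6-column BED (0-based, half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": records["chrom"],
            "start": records["start"].astype(int),
            "end": records["end"].astype(int),
            "name": records["name"],
            "score": 0,
            "strand": records.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a records frame (coordinates kept as-is)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed.columns = BED_COLS[: bed.shape[1]]
    return bed[["name", "chrom", "start", "end"] + (["strand"] if "strand" in bed else [])]


def filter_supported(counts: CountMatrix) -> list[str]:
    """piRNAs supported by at least one read in every library."""
    if counts.counts.empty:
        return []
    keep = (counts.counts > 0).all(axis=1)
    return list(counts.counts.index[keep])


def region_scan(
    de_table: pd.DataFrame,
    records: pd.DataFrame,
    window: int = 100_000,
    step: int = 50_000,
    min_members: int = 5,
    fc_threshold: float = -1.0,
) -> pd.DataFrame:
    """Sliding-window scan for contiguous blocks of downregulated piRNAs.

    A window is flagged when it contains at least ``min_members`` tested
    piRNAs whose median log2FC is <= ``fc_threshold``; overlapping flagged
    windows merge into maximal intervals.  Returns one row per merged
    interval: chrom, start, end, n_members, median_log2fc, flag.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    tested = de_table[de_table["status"] == "tested"] if "status" in de_table else de_table
    rec = records.set_index("name")
    missing = [n for n in tested.index if n not in rec.index]
    if missing:
        raise ValueError(f"coordinates missing for tested piRNAs: {missing[:5]}...")
    pos = rec.loc[tested.index]
    frame = pd.DataFrame(
        {
            "chrom": pos["chrom"],
            "start": pos["start"].astype(int),
            "log2fc": tested["log2fc"].to_numpy(),
        }
    ).sort_values(["chrom", "start"])

    flagged: list[tuple[str, int, int]] = []
    for chrom, sub in frame.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        fcs = sub["log2fc"].to_numpy()
        extent = int(starts.max()) + 1
        for w0 in range(0, max(extent, 1), step):
            w1 = w0 + window
            inside = (starts >= w0) & (starts < w1)
            if inside.sum() >= min_members and np.median(fcs[inside]) <= fc_threshold:
                flagged.append((chrom, w0, min(w1, extent)))
            if w0 + window >= extent:
                break

    merged: list[list] = []
    for chrom, w0, w1 in sorted(flagged):
        if merged and merged[-1][0] == chrom and w0 <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], w1)
        else:
            merged.append([chrom, w0, w1])

    rows = []
    for chrom, start, end in merged:
        inside = (frame["chrom"] == chrom) & (frame["start"] >= start) & (frame["start"] < end)
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "n_members": int(inside.sum()),
                "median_log2fc": float(np.median(frame.loc[inside, "log2fc"])),
                "flag": "dysregulated",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members",
                                       "median_log2fc", "flag"])


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two half-open intervals (planted-block recovery metric)."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0
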