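"""Read counting, CPM normalisation and expression filtering.

Counting rules:

* miRNAs — a read increments a dictionary entry iff the read's first 19 nt
  exactly equal that entry's first 19 nt.  Prefix matching deliberately
  captures 3' tailed and minorly 3'-trimmed isoforms under the parent miRNA.
  Reads shorter than the prefix are discarded (tallied); reads matching no
  entry are tallied as unassigned.
* piRNAs — perfect full-length match of the whole read to the whole
  reference sequence (21U-RNAs are counted strictly).
* spike-ins — same 19-nt prefix rule as miRNAs, but counted in a separate
  feature class and removed from the read stream so they never contaminate
  miRNA totals or the differential-expression input.

Normalisation is counts-per-million of the same feature class within a
library, with a pseudocount of 1 for miRNAs (0 for piRNAs and mRNAs), and
the expression filter keeps features whose mean wild-type CPM is >= 5.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    CpmMatrix,
    MirnaDictionary,
    SeqRead,
    WT,
    normalize_seq,
)

logger = logging.getLogger(__name__)

PREFIX_LEN = 19


class PrefixCollisionError(ValueError):
    """Distinct (unmerged) dictionary entries share a 19-nt prefix."""

    def __init__(self, collisions: dict[str, list[str]]):
        self.collisions = collisions
        msg = "; ".join(f"{p}: {','.join(names)}" for p, names in collisions.items())
        super().__init__(f"19-nt prefix collisions between distinct entries: {msg}")


def quality_filter(
    reads: Iterable[SeqRead], min_q: int = 30, min_frac: float = 100.0
) -> list[SeqRead]:
    """Keep reads in which >= ``min_frac`` percent of bases have quality >= ``min_q``.

    Defaults replicate a strict base-quality filter (every base must reach
    Q30).  Quality-free reads (plain text input) skip the stage with a
    logged notice — the exact-match stages downstream only need sequences.
    """
    kept: list[SeqRead] = []
    n_plain = 0
    for read in reads:
        if read.quality is None:
            n_plain += 1
            kept.append(read)
            continue
        q = np.asarray(read.quality)
        if q.size and 100.0 * (q >= min_q).sum() / q.size >= min_frac:
            kept.append(read)
    if n_plain:
        logger.info("quality_filter: %d quality-free reads passed through", n_plain)
    return kept


@dataclass
class LibraryCounts:
    """Per-library counting result with conservation tallies."""

    counts: dict[str, int]
    n_input: int = 0
    n_too_short: int = 0
    n_unassigned: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())


def _prefix_table(
    dictionary: MirnaDictionary, merge_prefix_collisions: bool = False
) -> dict[str, str]:
    """Map 19-nt prefix -> merged entry name; hard error on ambiguous prefixes."""
    table: dict[str, str] = {}
    owners: dict[str, list[str]] = {}
    for e in dictionary.entries:
        if len(e.sequence) < PREFIX_LEN:
            raise ValueError(f"dictionary entry {e.name} shorter than {PREFIX_LEN} nt")
        owners.setdefault(e.sequence[:PREFIX_LEN], []).append(e.name)
    collisions = {p: names for p, names in owners.items() if len(names) > 1}
    if collisions and not merge_prefix_collisions:
        raise PrefixCollisionError(collisions)
    for prefix, names in owners.items():
        table[prefix] = "|".join(names) if len(names) > 1 else names[0]
    return table


def count_mirnas(
    reads: Iterable[SeqRead | str],
    dictionary: MirnaDictionary,
    merge_prefix_collisions: bool = False,
) -> LibraryCounts:
    """Count reads against the miRNA dictionary by exact 19-nt prefix match."""
    table = _prefix_table(dictionary, merge_prefix_collisions)
    counts = {name: 0 for name in set(table.values())}
    n_in = n_short = n_un = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        n_in += 1
        if len(seq) < PREFIX_LEN:
            n_short += 1
            continue
        name = table.get(normalize_seq(seq[:PREFIX_LEN]))
        if name is None:
            n_un += 1
        else:
            counts[name] += 1
    return LibraryCounts(counts, n_in, n_short, n_un)


def count_pirnas(
    reads: Iterable[SeqRead | str], pirna_sequences: dict[str, str]
) -> LibraryCounts:
    """Count reads that perfectly match a full-length piRNA sequence."""
    lookup: dict[str, str] = {}
    for name, seq in pirna_sequences.items():
        seq = normalize_seq(seq)
        if seq in lookup:
            raise ValueError(f"duplicate piRNA sequence: {lookup[seq]} / {name}")
        lookup[seq] = name
    counts = {name: 0 for name in pirna_sequences}
    n_in = n_un = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        n_in += 1
        name = lookup.get(normalize_seq(seq))
        if name is None:
            n_un += 1
        else:
            counts[name] += 1
    return LibraryCounts(counts, n_in, 0, n_un)


def count_spikes(
    reads: Iterable[SeqRead], spikes: MirnaDictionary, dictionary: MirnaDictionary | None = None
) -> tuple[LibraryCounts, list[SeqRead]]:
    """Count spike-in reads (19-nt prefix rule) and strip them from the stream.

    Returns the spike counts and the remaining non-spike reads, so spike
    counts stay out of miRNA totals and of the differential-expression input.
    """
    if not spikes.entries:
        reads = list(reads)
        return LibraryCounts({}, len(reads), 0, len(reads)), reads
    table = _prefix_table(spikes)
    if dictionary is not None:
        mirna_prefixes = {e.sequence[:PREFIX_LEN] for e in dictionary.entries}
        shared = set(table) & mirna_prefixes
        if shared:
            raise ValueError(
                f"spike sequences share 19-nt prefixes with dictionary miRNAs: {sorted(shared)}"
            )
    counts = {name: 0 for name in set(table.values())}
    remaining: list[SeqRead] = []
    n_in = 0
    for read in reads:
        n_in += 1
        seq = normalize_seq(read.sequence[:PREFIX_LEN])
        name = table.get(seq) if len(read.sequence) >= PREFIX_LEN else None
        if name is None:
            remaining.append(read)
        else:
            counts[name] += 1
    lc = LibraryCounts(counts, n_in, 0, len(remaining))
    return lc, remaining


def assemble_count_matrix(
    per_library: dict[str, LibraryCounts],
    meta: pd.DataFrame,
    feature_class: str = "miRNA",
    features: list[str] | None = None,
) -> CountMatrix:
    """Merge per-library counting results into a CountMatrix."""
    if features is None:
        features = sorted({f for lc in per_library.values() for f in lc.counts})
    data = {
        lib: [per_library[lib].counts.get(f, 0) for f in features] for lib in meta.index
    }
    counts = pd.DataFrame(data, index=features, columns=list(meta.index))
    return CountMatrix(counts, meta, feature_class)


def cpm_normalize(counts: CountMatrix, pseudocount: int | None = None) -> CpmMatrix:
    """Counts-per-million within feature class: 1e6 * (c + pseudocount) / library total.

    The pseudocount enters the numerator only; the library total is the sum
    of raw counts of the same feature class.  Default pseudocount is 1 for
    miRNAs and 0 otherwise.
    """
    if pseudocount is None:
        pseudocount = 1 if counts.feature_class == "miRNA" else 0
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"zero {counts.feature_class} total in libraries: {zero}")
    values = 1e6 * (counts.counts + pseudocount) / totals
    return CpmMatrix(values, counts.meta, pseudocount, counts.feature_class)


def expression_filter(
    cpm: CpmMatrix,
    threshold: float = 5.0,
    stage: str | None = None,
    inclusive: bool = True,
) -> list[str]:
    """Features whose mean wild-type CPM reaches the threshold (default >= 5)."""
    mean_wt = cpm.wt_mean(stage)
    keep = mean_wt >= threshold if inclusive else mean_wt > threshold
    return list(mean_wt.index[keep])


@dataclass
class CountingReport:
    """Bookkeeping for one library run through the full counting stack."""

    library: str
    n_input: int = 0
    n_spike: int = 0
    n_mirna: int = 0
    n_too_short: int = 0
    n_unassigned: int = 0
    extras: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        return self.n_input == (
            self.n_spike + self.n_mirna + self.n_too_short + self.n_unassigned
        )


def count_library(
    reads: Iterable[SeqRead],
    dictionary: MirnaDictionary,
    spikes: MirnaDictionary | None = None,
    library: str = "lib",
    apply_quality_filter: bool = True,
    min_q: int = 30,
    min_frac: float = 100.0,
) -> tuple[LibraryCounts, LibraryCounts | None, CountingReport]:
    """Full per-library pipeline: quality filter -> spike removal -> miRNA counting."""
    reads = list(reads)
    if apply_quality_filter:
        reads = quality_filter(reads, min_q=min_q, min_frac=min_frac)
    spike_lc = None
    if spikes is not None and spikes.entries:
        spike_lc, reads = count_spikes(reads, spikes, dictionary)
    mirna_lc = count_mirnas(reads, dictionary)
    report = CountingReport(
        library=library,
        n_input=mirna_lc.n_input + (spike_lc.n_assigned if spike_lc else 0),
        n_spike=spike_lc.n_assigned if spike_lc else 0,
        n_mirna=mirna_lc.n_assigned,
        n_too_short=mirna_lc.n_too_short,
        n_unassigned=mirna_lc.n_unassigned,
    )
    return mirna_lc, spike_lc, report
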