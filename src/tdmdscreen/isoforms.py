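"""Tail/trim isomiR profiling by whole-read exact matching, with spike-in
error calibration.

Unlike the 19-nt prefix counting used for abundance, isoform profiling
expands each mature miRNA into a fixed panel of 14 exact strings — the
full-length sequence, 3' trims of 1-4 nt, 5' trims of 1-2 nt, and the seven
most common nontemplated 3' tails (A, AA, U, UU, UUU, AU, UA) — and
tabulates perfect whole-read matches to each.  The panel spans the most
common modified species rather than an exhaustive isomiR catalogue; reads
matching none of the strings (e.g. combined trim+tail species) are excluded
from the denominator.  Strings claimed by more than one miRNA are recorded
in an ambiguity ledger and excluded from counting.

Synthetic spike-in oligos are full-length by construction, so their isoform
profile measures the apparent tailing/trimming introduced by library
preparation and sequencing; those per-class rates serve as the background
against which biological fraction differences are judged.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MirnaDictionary, SeqRead, normalize_seq

#: The 14 isoform classes profiled per miRNA.
ISOFORM_CLASSES: tuple[str, ...] = (
    "FL",
    "3t1", "3t2", "3t3", "3t4",
    "5t1", "5t2",
    "+A", "+AA", "+U", "+UU", "+UUU", "+AU", "+UA",
)

#: Spike classes interpreted as miscalls (spikes are full-length by synthesis).
MISCALL_CLASSES: tuple[str, ...] = ("+A", "+AA", "+U", "+UU", "+UUU", "3t1", "3t2")


def isoform_sequence(mature: str, iso_class: str) -> str:
    """Exact sequence of one isoform class of a mature miRNA (RNA alphabet)."""
    mature = normalize_seq(mature)
    if iso_class == "FL":
        return mature
    if iso_class.startswith("3t"):
        n = int(iso_class[2:])
        if n >= len(mature):
            raise ValueError(f"3' trim {n} >= mature length {len(mature)}")
        return mature[:-n]
    if iso_class.startswith("5t"):
        n = int(iso_class[2:])
        if n >= len(mature):
            raise ValueError(f"5' trim {n} >= mature length {len(mature)}")
        return mature[n:]
    if iso_class.startswith("+"):
        return mature + iso_class[1:]
    raise ValueError(f"unknown isoform class: {iso_class}")


@dataclass
class IsoformDictionary:
    """Expanded per-miRNA isoform strings plus the cross-miRNA ambiguity ledger."""

    classes: tuple[str, ...]
    strings: dict[str, dict[str, str]]  # miRNA -> class -> sequence
    ambiguous: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def lookup(self) -> dict[str, tuple[str, str]]:
        """Unambiguous sequence -> (miRNA, class) table."""
        table: dict[str, tuple[str, str]] = {}
        for name, per_class in self.strings.items():
            for cls, seq in per_class.items():
                if seq not in self.ambiguous:
                    table[seq] = (name, cls)
        return table


def expand_isoform_dictionary(
    dictionary: MirnaDictionary, classes: Iterable[str] = ISOFORM_CLASSES
) -> IsoformDictionary:
    """Expand every dictionary entry into its isoform class strings.

    Cross-miRNA string collisions (e.g. one miRNA's 3'-trim-1 equalling
    another's full-length sequence) are detected and ledgered as ambiguous;
    a collision *within* one miRNA means a degenerate mature sequence and is
    an error.
    """
    classes = tuple(classes)
    max_trim = max(
        (int(c[2:]) for c in classes if c[0] in "35" and c[1] == "t"), default=0
    )
    strings: dict[str, dict[str, str]] = {}
    owners: dict[str, list[tuple[str, str]]] = {}
    for e in dictionary.entries:
        if len(e.sequence) <= max_trim + 1:
            raise ValueError(
                f"{e.name}: mature length {len(e.sequence)} too short for trim depth {max_trim}"
            )
        per_class = {cls: isoform_sequence(e.sequence, cls) for cls in classes}
        if len(set(per_class.values())) != len(per_class):
            raise ValueError(f"{e.name}: degenerate mature sequence, isoform strings collide")
        strings[e.name] = per_class
        for cls, seq in per_class.items():
            owners.setdefault(seq, []).append((e.name, cls))
    ambiguous = {
        seq: who for seq, who in owners.items() if len({w[0] for w in who}) > 1
    }
    return IsoformDictionary(classes, strings, ambiguous)


@dataclass
class IsoformProfile:
    """Per-miRNA isoform class counts and fractions for one library."""

    counts: pd.DataFrame  # miRNA x class, int
    n_ambiguous: int = 0
    n_unmatched: int = 0

    def fractions(self) -> pd.DataFrame:
        """Class fractions per miRNA; rows with zero total are NaN (flagged via `defined`)."""
        totals = self.counts.sum(axis=1)
        frac = self.counts.div(totals.where(totals > 0), axis=0)
        return frac

    @property
    def defined(self) -> pd.Series:
        """True where the miRNA has at least one isoform-matching read."""
        return self.counts.sum(axis=1) > 0


def profile_isoforms(
    reads: Iterable[SeqRead | str], iso_dict: IsoformDictionary
) -> IsoformProfile:
    """Tabulate whole-read exact matches to the expanded isoform strings."""
    lookup = iso_dict.lookup()
    ambiguous = iso_dict.ambiguous
    names = list(iso_dict.strings)
    counts = pd.DataFrame(
        0, index=names, columns=list(iso_dict.classes), dtype=np.int64
    )
    n_amb = n_un = 0
    for read in reads:
        seq = normalize_seq(read if isinstance(read, str) else read.sequence)
        hit = lookup.get(seq)
        if hit is not None:
            counts.loc[hit[0], hit[1]] += 1
        elif seq in ambiguous:
            n_amb += 1
        else:
            n_un += 1
    return IsoformProfile(counts, n_amb, n_un)


@dataclass
class SpikeCalibration:
    """Apparent tail/trim miscall rates measured on full-length spike-ins."""

    rates: pd.DataFrame  # spike x miscall class, fractions
    n_reads: pd.Series  # spike -> total isoform-matching reads

    def background(self) -> pd.Series:
        """Per-class background: the maximum miscall rate across spikes."""
        return self.rates.max(axis=0)


def spike_error_calibration(
    reads: Iterable[SeqRead | str], spikes: MirnaDictionary
) -> SpikeCalibration:
    """Measure per-class miscall rates from spike-in reads of one library."""
    iso = expand_isoform_dictionary(spikes)
    profile = profile_isoforms(reads, iso)
    totals = profile.counts.sum(axis=1)
    if (totals == 0).all():
        raise ValueError("no spike reads: miscall calibration impossible")
    frac = profile.fractions()[list(MISCALL_CLASSES)]
    return SpikeCalibration(frac.fillna(0.0), totals)


def compare_isoform_fractions(
    profile_wt: IsoformProfile,
    profile_mut: IsoformProfile,
    calibration: SpikeCalibration | None = None,
) -> pd.DataFrame:
    """Per miRNA x class: WT fraction, mutant fraction, difference, background flag.

    Classes whose fractions in both genotypes fall below the calibrated
    miscall background are flagged ``within_error``: differences there are
    indistinguishable from library-preparation artefacts.
    """
    if list(profile_wt.counts.columns) != list(profile_mut.counts.columns):
        raise ValueError("profiles use different isoform class sets")
    fw = profile_wt.fractions()
    fm = profile_mut.fractions()
    rows = []
    background = calibration.background() if calibration is not None else pd.Series(dtype=float)
    for name in fw.index:
        for cls in fw.columns:
            wt_f, mut_f = fw.loc[name, cls], fm.loc[name, cls]
            bg = float(background.get(cls, 0.0))
            within = bool(
                calibration is not None
                and not np.isnan(wt_f)
                and not np.isnan(mut_f)
                and wt_f <= bg
                and mut_f <= bg
            )
            rows.append(
                {
                    "mirna": name,
                    "iso_class": cls,
                    "wt_fraction": wt_f,
                    "mut_fraction": mut_f,
                    "difference": mut_f - wt_f,
                    "background": bg,
                    "within_error": within,
                }
            )
    return pd.DataFrame(rows)
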