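"""Shared in-memory containers and file I/O for the small-RNA screening pipeline.

The pipeline works with three kinds of objects throughout:

* :class:`MirnaDictionary` — the curated set of mature miRNA guide/passenger
  sequences (plus, reusing the same machinery, spike-in oligos), with
  identical-sequence merging and a passenger blacklist.
* :class:`CountMatrix` — integer read counts, features x libraries, with
  per-library metadata (genotype, stage, replicate) and a feature class
  (miRNA | piRNA | spike | mRNA).
* :class:`CpmMatrix` — counts-per-million normalisation of a CountMatrix.

Sequences are stored as RNA (U) internally; reads arrive as DNA (T).  All
matching happens after a single declared T->U, uppercase normalisation,
:func:`normalize_seq`.
"""

from __future__ import annotations

import io
import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_T2U = str.maketrans("Tt", "Uu")

WT = "WT"
MUTANT = "mutant"


def normalize_seq(seq: str) -> str:
    """Uppercase and convert T to U: the single declared DNA->RNA normalisation."""
    return seq.upper().translate(_T2U).upper()


class SeqRead(NamedTuple):
    """A sequencing read: sequence string plus optional per-base Phred qualities."""

    sequence: str
    quality: tuple[int, ...] | None = None


def read_fastq(path) -> Iterator[SeqRead]:
    """Yield reads from a FASTQ file (qualities attached)."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SeqRead(str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))


def read_plain(path) -> Iterator[SeqRead]:
    """Yield quality-free reads from a one-sequence-per-line text file."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield SeqRead(line, None)


@dataclass(frozen=True)
class MirnaEntry:
    """One mature miRNA strand in the dictionary."""

    name: str
    sequence: str  # RNA alphabet, uppercase
    role: str = "guide"  # guide | passenger
    family: str = ""
    locus: str = ""


@dataclass
class MirnaDictionary:
    """Curated mature miRNA dictionary with identical-sequence merging.

    Entries that share a full mature sequence are merged under a single name
    (joined with ``|`` unless the first name is kept, mirroring the miR-44/45
    convention of naming the merged entry after one member); the merge map
    records which original names each merged entry covers.  Blacklisted names
    (identical passenger strands deliberately excluded from analysis) are
    dropped before merging.
    """

    entries: list[MirnaEntry]
    merge_map: dict[str, list[str]] = field(default_factory=dict)
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.entries = [
            MirnaEntry(e.name, normalize_seq(e.sequence), e.role, e.family, e.locus)
            for e in self.entries
        ]

    # -- construction -------------------------------------------------

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[MirnaEntry],
        blacklist: Iterable[str] = (),
    ) -> "MirnaDictionary":
        """Build a merged dictionary: drop blacklisted entries, merge identical sequences."""
        blacklist = frozenset(blacklist)
        kept = [e for e in entries if e.name not in blacklist]
        by_seq: dict[str, list[MirnaEntry]] = {}
        for e in kept:
            by_seq.setdefault(normalize_seq(e.sequence), []).append(e)
        merged_entries: list[MirnaEntry] = []
        merge_map: dict[str, list[str]] = {}
        for seq, group in by_seq.items():
            first = group[0]
            if len(group) == 1:
                merged_entries.append(first)
            else:
                names = [g.name for g in group]
                merged_entries.append(
                    MirnaEntry(first.name, seq, first.role, first.family, first.locus)
                )
                merge_map[first.name] = names
                logger.info(
                    "merged %d identical sequences under %s: %s",
                    len(group), first.name, ",".join(names),
                )
        return cls(merged_entries, merge_map, blacklist)

    # -- queries ------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def sequences(self) -> dict[str, str]:
        return {e.name: e.sequence for e in self.entries}

    def guides(self) -> list[MirnaEntry]:
        return [e for e in self.entries if e.role == "guide"]

    def passengers_of(self, locus: str) -> list[MirnaEntry]:
        """All passenger strands annotated at a locus (miR-44/45-like loci have two)."""
        return [e for e in self.entries if e.locus == locus and e.role == "passenger"]

    def entry(self, name: str) -> MirnaEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def validate(self, min_len: int = 19) -> None:
        seqs = [e.sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("dictionary contains duplicate sequences after merging")
        short = [e.name for e in self.entries if len(e.sequence) < min_len]
        if short:
            raise ValueError(f"entries shorter than {min_len} nt: {short}")

    # -- I/O -----------------------------------------------------------

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.name} role={e.role} family={e.family} locus={e.locus}\n")
                fh.write(e.sequence + "\n")

    @classmethod
    def from_fasta(cls, path, blacklist: Iterable[str] = ()) -> "MirnaDictionary":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            attrs = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            entries.append(
                MirnaEntry(
                    rec.id,
                    str(rec.seq),
                    attrs.get("role", "guide"),
                    attrs.get("family", ""),
                    attrs.get("locus", ""),
                )
            )
        return cls.from_entries(entries, blacklist=blacklist)


# ---------------------------------------------------------------------------
# Count matrices


_META_COLS = ("genotype", "stage", "replicate")


@dataclass
class CountMatrix:
    """Integer read counts, features x libraries, with library metadata.

    ``counts`` is a features-by-libraries DataFrame of non-negative integers;
    ``meta`` is indexed by library label and carries genotype / stage /
    replicate; ``feature_class`` labels what is being counted so that spike
    counts are never mixed into miRNA totals.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    feature_class: str = "miRNA"

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("count columns and metadata index must align")
        missing = [c for c in _META_COLS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"library metadata missing columns: {missing}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    # -- selection -----------------------------------------------------

    def libraries(self, genotype: str | None = None, stage: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if genotype is not None:
            mask &= self.meta["genotype"] == genotype
        if stage is not None:
            mask &= self.meta["stage"] == stage
        return list(self.meta.index[mask])

    def subset_libraries(self, libs: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[libs], self.meta.loc[libs], self.feature_class)

    def subset_features(self, feats) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feats)], self.meta, self.feature_class)

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.meta["stage"]))

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write counts with a ``#``-prefixed metadata header block."""
        with open(path, "w") as fh:
            fh.write(f"#feature_class\t{self.feature_class}\n")
            for col in _META_COLS:
                vals = "\t".join(str(v) for v in self.meta[col])
                fh.write(f"#{col}\t{vals}\n")
            self.counts.rename_axis("feature").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        header: dict[str, list[str]] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, *vals = line[1:].rstrip("\n").split("\t")
                    header[key] = vals
                else:
                    body.write(line)
        body.seek(0)
        counts = pd.read_csv(body, sep="\t", index_col=0)
        counts.index.name = None
        meta = pd.DataFrame(
            {col: header.get(col, [""] * counts.shape[1]) for col in _META_COLS},
            index=counts.columns,
        )
        if "replicate" in header:
            meta["replicate"] = [int(v) for v in header["replicate"]]
        return cls(counts, meta, header.get("feature_class", ["miRNA"])[0])


@dataclass
class CpmMatrix:
    """Counts-per-million view of a CountMatrix (same axes)."""

    values: pd.DataFrame
    meta: pd.DataFrame
    pseudocount: int = 1
    feature_class: str = "miRNA"

    def wt_mean(self, stage: str | None = None) -> pd.Series:
        mask = self.meta["genotype"] == WT
        if stage is not None:
            mask &= self.meta["stage"] == stage
        libs = list(self.meta.index[mask])
        if not libs:
            raise ValueError("no wild-type libraries in CPM matrix")
        return self.values[libs].mean(axis=1)


def make_library_meta(
    genotypes: Iterable[str], stages: Iterable[str], replicates: Iterable[int]
) -> pd.DataFrame:
    """Build a metadata frame with canonical library labels genotype_stage_repN."""
    rows = list(zip(genotypes, stages, replicates))
    labels = [f"{g}_{s}_rep{r}" for g, s, r in rows]
    return pd.DataFrame(rows, columns=list(_META_COLS), index=labels)
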