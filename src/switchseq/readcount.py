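"""Read demultiplexing, per-variant counting, and the DNA-coverage filter."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .library_model import ControlRibozyme, LibraryTemplate, VariantID, match_read

__all__ = [
    "ConditionKey",
    "CountTable",
    "read_fastq",
    "demultiplex",
    "match_stream",
    "count_variants",
    "filter_min_dna",
]

# A column of the count table: (assay, ligand condition, replicate index),
# e.g. ("DNA", "minus", 1).
ConditionKey = tuple[str, str, int]

_COLUMN_NAMES = ("assay", "condition", "replicate")


def _key_to_str(key: ConditionKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


def _str_to_key(s: str) -> ConditionKey:
    assay, condition, rep = s.split(":")
    return (assay, condition, int(rep))


@dataclass
class CountTable:
    """Per-variant read counts keyed by (assay, condition, replicate).

    ``counts`` is indexed by variant key (loop sequence or control name) with
    a 3-level column MultiIndex. Controls are tracked by name so downstream
    filters can exempt them.
    """

    counts: pd.DataFrame
    controls: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts must have (assay, condition, replicate) columns")
        self.counts.columns = self.counts.columns.set_names(_COLUMN_NAMES)
        self.counts.index.name = "variant"
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.controls = frozenset(self.controls)
        missing = self.controls - set(self.counts.index)
        if missing:
            # every control must be present as a row, possibly all-zero
            new_index = self.counts.index.append(pd.Index(sorted(missing)))
            self.counts = self.counts.reindex(new_index, fill_value=0)

    @property
    def variants(self) -> pd.Index:
        return self.counts.index

    def assay(self, assay: str) -> pd.DataFrame:
        """Counts for one assay, columns (condition, replicate)."""
        return self.counts.xs(assay, axis=1, level="assay")

    def is_control(self, variant: str) -> bool:
        return variant in self.controls

    def to_tsv(self, path) -> None:
        flat = self.counts.copy()
        flat.columns = [_key_to_str(k) for k in flat.columns]
        flat.insert(0, "is_control", [v in self.controls for v in flat.index])
        flat.index.name = "variant"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        flat = pd.read_csv(path, sep="\t", index_col="variant")
        controls = frozenset(flat.index[flat.pop("is_control").astype(bool)])
        flat.columns = pd.MultiIndex.from_tuples(
            [_str_to_key(c) for c in flat.columns], names=_COLUMN_NAMES)
        return cls(flat, controls)


def read_fastq(path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzipped or plain)."""
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        for rec in SeqIO.parse(path, "fastq"):
            yield str(rec.seq)


def demultiplex(
    reads: Iterable[str],
    barcode_map: Mapping[str, ConditionKey],
) -> tuple[dict[ConditionKey, list[str]], int]:
    """Assign reads to conditions by exact 5' barcode match.

    Barcodes must be unique and of equal length; the barcode is stripped from
    each assigned read. Returns the per-condition read lists and the number
    of discarded (unassigned) reads.
    """
    if len(set(barcode_map)) != len(barcode_map):
        raise ValueError("duplicate barcodes")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError("barcodes must have equal length")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("conditions must be unique per barcode")
    (blen,) = lengths
    streams: dict[ConditionKey, list[str]] = {k: [] for k in barcode_map.values()}
    discarded = 0
    for read in reads:
        key = barcode_map.get(read[:blen].upper())
        if key is None:
            discarded += 1
        else:
            streams[key].append(read[blen:])
    return streams, discarded


def match_stream(
    streams: Mapping[ConditionKey, Iterable[str]],
    template: LibraryTemplate,
    controls: Iterable[ControlRibozyme] = (),
    max_mismatches: int = 0,
) -> Iterator[tuple[ConditionKey, VariantID]]:
    """Run architecture matching over demultiplexed streams, yielding
    (condition, variant) pairs for matching reads."""
    controls = tuple(controls)
    for key, reads in streams.items():
        for read in reads:
            vid = match_read(read, template, controls, max_mismatches)
            if vid is not None:
                yield key, vid


def count_variants(
    matched: Iterable[tuple[ConditionKey, VariantID]],
    controls: Iterable[ControlRibozyme] = (),
    conditions: Iterable[ConditionKey] | None = None,
) -> CountTable:
    """Tally matched reads into a CountTable.

    ``conditions`` fixes the column set (useful so empty conditions still
    appear); otherwise columns are those observed.
    """
    tallies: dict[ConditionKey, dict[str, int]] = {}
    if conditions is not None:
        for key in conditions:
            tallies[key] = {}
    for key, vid in matched:
        col = tallies.setdefault(key, {})
        col[vid.key] = col.get(vid.key, 0) + 1
    if tallies:
        frame = pd.DataFrame(tallies).fillna(0).astype(int)
        frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=_COLUMN_NAMES)
    else:
        frame = pd.DataFrame(
            index=pd.Index([], dtype=object),
            columns=pd.MultiIndex.from_tuples([], names=_COLUMN_NAMES))
    frame = frame.sort_index().sort_index(axis=1)
    return CountTable(frame, frozenset(c.name for c in controls))


def filter_min_dna(
    table: CountTable, threshold: int = 100
) -> tuple[CountTable, list[str]]:
    """Drop variants whose DNA count falls below ``threshold`` in any
    condition/replicate. Controls are always retained. Returns the filtered
    table and the list of removed variant keys."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dna = table.assay("DNA")
    ok = (dna >= threshold).all(axis=1)
    keep = ok | table.counts.index.isin(table.controls)
    removed = sorted(table.counts.index[~keep])
    return CountTable(table.counts.loc[keep].copy(), table.controls), removed
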