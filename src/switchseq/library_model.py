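"""Ribozyme-switch library architecture: templates, enumeration, read matching.

A switch is a self-cleaving hammerhead ribozyme whose stem loops carry (a) a
ligand-binding aptamer and (b) a short randomized loop. A library template
pins down the fixed flanks, the catalytic core, and the per-design "overlap"
bases that join the slots to their neighbours; exactly one slot (loop I or
loop II) is degenerate. All sequences are held internally in DNA space
(U mapped to T on ingest).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DNA_BASES",
    "DEFAULT_FLANK5",
    "CATALYTIC_CORE",
    "DEFAULT_FLANK3",
    "DEFAULT_OVERLAPS",
    "as_dna",
    "VariantID",
    "ControlRibozyme",
    "LibraryTemplate",
    "build_switch_template",
    "render_control",
    "library_diversity",
    "match_read",
    "write_fasta",
    "read_fasta",
    "read_controls_fasta",
    "write_controls_fasta",
]

DNA_BASES = "ACGT"

#: Fixed 5' context: leader followed by the stem I closing strand.
DEFAULT_FLANK5 = "AAACAAACAAAGCTGTCACCG"
#: Conserved catalytic core between the two stem loops.
CATALYTIC_CORE = "CGGTCTGATGAGTC"
#: Fixed 3' context: stem III closing strand plus the downstream A-rich tail.
DEFAULT_FLANK3 = "GACGAAACAGC" + "AAAAAGAAAAATAAAAA"

#: Default joining bases flanking each slot (two either side of loop I, one
#: either side of loop II) -- the positions tuned per design.
DEFAULT_OVERLAPS: Mapping[str, str] = {
    "slot1_pre": "GA",
    "slot1_post": "TC",
    "slot2_pre": "C",
    "slot2_post": "G",
}


def as_dna(seq: str, allow_n: bool = False) -> str:
    """Normalize a nucleotide string to uppercase DNA (U -> T).

    Raises ``ValueError`` on characters outside {A,C,G,T} (plus N when
    ``allow_n``).
    """
    s = str(seq).upper().replace("U", "T")
    allowed = set(DNA_BASES) | ({"N"} if allow_n else set())
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class VariantID:
    """Identity of a library member: its degenerate-loop sequence, or a
    control ribozyme's name."""

    loop_seq: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.is_control:
            object.__setattr__(self, "loop_seq", as_dna(self.loop_seq))

    @property
    def key(self) -> str:
        return self.loop_seq

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.loop_seq


@dataclass(frozen=True)
class ControlRibozyme:
    """Spiked-in ribozyme of known activity used for calibration."""

    name: str
    sequence: str
    reference_rfu: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_dna(self.sequence))
        if self.reference_rfu <= 0:
            raise ValueError("reference_rfu must be > 0")


@dataclass(frozen=True)
class LibraryTemplate:
    """Fixed architecture of a switch library with one degenerate slot.

    Rendered sequence for a loop choice L is::

        flank5 + slot1_pre + slot1 + slot1_post + core
               + slot2_pre + slot2 + slot2_post + flank3

    where the degenerate slot (``stem1_slot is None`` or ``stem2_slot is
    None``) is replaced by L.
    """

    flank5: str = DEFAULT_FLANK5
    stem1_slot: str | None = None
    core: str = CATALYTIC_CORE
    stem2_slot: str | None = None
    flank3: str = DEFAULT_FLANK3
    slot1_pre: str = DEFAULT_OVERLAPS["slot1_pre"]
    slot1_post: str = DEFAULT_OVERLAPS["slot1_post"]
    slot2_pre: str = DEFAULT_OVERLAPS["slot2_pre"]
    slot2_post: str = DEFAULT_OVERLAPS["slot2_post"]
    degenerate_lengths: frozenset[int] = frozenset({5})

    def __post_init__(self) -> None:
        if (self.stem1_slot is None) == (self.stem2_slot is None):
            raise ValueError("exactly one slot must be degenerate (None)")
        for name in ("flank5", "core", "flank3", "slot1_pre", "slot1_post",
                     "slot2_pre", "slot2_post"):
            object.__setattr__(self, name, as_dna(getattr(self, name)))
        for name in ("stem1_slot", "stem2_slot"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, as_dna(val))
        lengths = frozenset(int(x) for x in self.degenerate_lengths)
        if any(l < 0 for l in lengths):
            raise ValueError("degenerate lengths must be >= 0")
        object.__setattr__(self, "degenerate_lengths", lengths)

    @property
    def degenerate_slot(self) -> str:
        return "stem1" if self.stem1_slot is None else "stem2"

    @property
    def prefix(self) -> str:
        """Fixed sequence upstream of the degenerate loop."""
        if self.degenerate_slot == "stem1":
            return self.flank5 + self.slot1_pre
        return (self.flank5 + self.slot1_pre + self.stem1_slot
                + self.slot1_post + self.core + self.slot2_pre)

    @property
    def suffix(self) -> str:
        """Fixed sequence downstream of the degenerate loop."""
        if self.degenerate_slot == "stem1":
            return (self.slot1_post + self.core + self.slot2_pre
                    + self.stem2_slot + self.slot2_post + self.flank3)
        return self.slot2_post + self.flank3

    def render(self, loop: str) -> str:
        """Full sequence with the degenerate slot set to ``loop``."""
        loop = as_dna(loop)
        if len(loop) not in self.degenerate_lengths:
            raise ValueError(
                f"loop length {len(loop)} not in {sorted(self.degenerate_lengths)}")
        return self.prefix + loop + self.suffix

    def enumerate_variants(self) -> Iterator[VariantID]:
        """All variant identities, shortest loops first, lexicographic."""
        for length in sorted(self.degenerate_lengths):
            for combo in itertools.product(DNA_BASES, repeat=length):
                yield VariantID("".join(combo))

    def enumerate_sequences(self) -> Iterator[tuple[VariantID, str]]:
        for vid in self.enumerate_variants():
            yield vid, self.render(vid.loop_seq)


def build_switch_template(
    aptamer: str,
    placement: str = "loopI",
    degenerate_lengths: Iterable[int] = (4, 5),
    overlap_bases: Mapping[str, str] | None = None,
    flank5: str = DEFAULT_FLANK5,
    core: str = CATALYTIC_CORE,
    flank3: str = DEFAULT_FLANK3,
) -> LibraryTemplate:
    """Build a switch library template with the aptamer on one stem loop and
    a degenerate loop on the other.

    Parameters
    ----------
    aptamer
        Aptamer sequence (RNA accepted, mapped to DNA). May be empty for
        plain-ribozyme templates where the fixed slot is just the overlaps.
    placement
        ``"loopI"`` places the aptamer in stem loop I (degenerate loop II),
        ``"loopII"`` the reverse.
    degenerate_lengths
        Allowed lengths of the randomized loop.
    overlap_bases
        Optional override of the per-design joining bases; keys
        ``slot1_pre``, ``slot1_post``, ``slot2_pre``, ``slot2_post``.
    """
    if placement not in ("loopI", "loopII"):
        raise ValueError("placement must be 'loopI' or 'loopII'")
    ov = dict(DEFAULT_OVERLAPS)
    if overlap_bases:
        unknown = set(overlap_bases) - set(ov)
        if unknown:
            raise ValueError(f"unknown overlap keys: {sorted(unknown)}")
        ov.update(overlap_bases)
    aptamer = as_dna(aptamer)
    if placement == "loopI":
        stem1, stem2 = aptamer, None
    else:
        stem1, stem2 = None, aptamer
    return LibraryTemplate(
        flank5=flank5, core=core, flank3=flank3,
        stem1_slot=stem1, stem2_slot=stem2,
        slot1_pre=ov["slot1_pre"], slot1_post=ov["slot1_post"],
        slot2_pre=ov["slot2_pre"], slot2_post=ov["slot2_post"],
        degenerate_lengths=frozenset(degenerate_lengths),
    )


def render_control(
    loop1: str,
    loop2: str,
    flank5: str = DEFAULT_FLANK5,
    core: str = CATALYTIC_CORE,
    flank3: str = DEFAULT_FLANK3,
    overlap_bases: Mapping[str, str] | None = None,
) -> str:
    """Render the fully fixed control-ribozyme architecture with the given
    loop I and loop II sequences."""
    ov = dict(DEFAULT_OVERLAPS)
    if overlap_bases:
        ov.update(overlap_bases)
    return (as_dna(flank5) + ov["slot1_pre"] + as_dna(loop1) + ov["slot1_post"]
            + as_dna(core) + ov["slot2_pre"] + as_dna(loop2) + ov["slot2_post"]
            + as_dna(flank3))


def library_diversity(template: LibraryTemplate) -> int:
    """Number of unique variants: sum over allowed lengths L of 4**L."""
    return sum(4 ** l for l in template.degenerate_lengths)


def _find_with_mismatches(read: str, pattern: str, max_mm: int) -> list[int]:
    """Start positions where ``pattern`` occurs in ``read`` with at most
    ``max_mm`` substitutions (N in the read never matches)."""
    hits = []
    for start in range(len(read) - len(pattern) + 1):
        mm = 0
        for a, b in zip(read[start:start + len(pattern)], pattern):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            hits.append(start)
    return hits


def match_read(
    read: str,
    template: LibraryTemplate,
    controls: Iterable[ControlRibozyme] = (),
    max_mismatches: int = 0,
) -> VariantID | None:
    """Match a read against spiked-in controls, then the library architecture.

    Controls are matched first by exact substring so a control can never
    parse as a variant. For library matching, the fixed prefix and suffix
    around the degenerate slot must occur exactly (or within
    ``max_mismatches`` substitutions each) with a loop of an allowed length
    in between. Returns ``None`` when nothing matches.
    """
    read = as_dna(read, allow_n=True)
    for ctl in controls:
        if ctl.sequence in read:
            return VariantID(ctl.name, is_control=True)

    prefix, suffix = template.prefix, template.suffix
    if max_mismatches == 0:
        start = read.find(prefix)
        while start != -1:
            loop_start = start + len(prefix)
            for length in sorted(template.degenerate_lengths):
                end = loop_start + length
                if read.startswith(suffix, end):
                    loop = read[loop_start:end]
                    if set(loop) <= set(DNA_BASES):
                        return VariantID(loop)
            start = read.find(prefix, start + 1)
        return None

    for start in _find_with_mismatches(read, prefix, max_mismatches):
        loop_start = start + len(prefix)
        for length in sorted(template.degenerate_lengths):
            end = loop_start + length
            if end + len(suffix) > len(read):
                continue
            window = read[end:end + len(suffix)]
            mm = sum(a != b for a, b in zip(window, suffix))
            if mm <= max_mismatches:
                loop = read[loop_start:end]
                if set(loop) <= set(DNA_BASES):
                    return VariantID(loop)
    return None


# -- FASTA I/O ---------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_controls_fasta(controls: Iterable[ControlRibozyme], path) -> None:
    recs = [
        SeqRecord(Seq(c.sequence), id=c.name, description=f"rfu={c.reference_rfu:g}")
        for c in controls
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_controls_fasta(path) -> list[ControlRibozyme]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rfu = 100.0
        for token in rec.description.split():
            if token.startswith("rfu="):
                rfu = float(token[4:])
        out.append(ControlRibozyme(rec.id, str(rec.seq), reference_rfu=rfu))
    return out
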