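"""Seeded simulator for switch-screen data.

Generates ground-truth libraries (per-variant uncleaved mRNA fractions and
switching strengths), DNA/RNA read counts with copy-number dispersion,
architecture-bearing reads, and sorted-bin FACS counts -- the statistical
structure the analysis stages assume, so every stage is testable without
external data.

Model: the steady-state mRNA level of a variant is proportional to its
uncleaved fraction f. Without ligand f = f0; ligand inhibits cleavage
multiplicatively toward 1, f1 = f0 + (1 - f0) * s, so f1 >= f0 and the true
activation ratio is f1/f0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .facsseq import BinnedSortData
from .library_model import (
    DNA_BASES,
    ControlRibozyme,
    LibraryTemplate,
    build_switch_template,
    render_control,
)
from .readcount import ConditionKey, CountTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_controls",
    "default_template",
    "default_barcodes",
    "simulate_ground_truth",
    "expected_counts",
    "simulate_counts",
    "write_fastq",
    "auto_bin_edges",
    "simulate_reads",
    "simulate_facs",
]

#: (name, uncleaved fraction) of the default spiked-in control set; the
#: non-cleaving reference has f = 1.
DEFAULT_CONTROL_FRACTIONS: tuple[tuple[str, float], ...] = (
    ("sTRSVctl", 1.0),
    ("ctlA", 0.6),
    ("ctlB", 0.3),
    ("ctlC", 0.12),
    ("ctlD", 0.05),
)

_CONTROL_LOOPS = {
    "sTRSVctl": ("TTTGGGT", "CCACC"),
    "ctlA": ("AGTCAGT", "GGTGG"),
    "ctlB": ("CACTGAC", "TTCTT"),
    "ctlC": ("GTGACTG", "AAGAA"),
    "ctlD": ("TCAGTCA", "CGGGC"),
}


def default_controls() -> list[tuple[ControlRibozyme, float]]:
    """Default control set: (ControlRibozyme, true uncleaved fraction)."""
    out = []
    for name, f in DEFAULT_CONTROL_FRACTIONS:
        loop1, loop2 = _CONTROL_LOOPS[name]
        seq = render_control(loop1, loop2)
        out.append((ControlRibozyme(name, seq, reference_rfu=100.0 * f), f))
    return out


def default_template(loop_lengths: Sequence[int] = (5,)) -> LibraryTemplate:
    """A stem-loop-II randomized template with a short stand-in aptamer."""
    return build_switch_template(
        aptamer="ATACCAGCATCGTCTTGATGCCCTTGGCAGT",
        placement="loopI",
        degenerate_lengths=loop_lengths,
    )


def default_barcodes(keys: Sequence[ConditionKey]) -> dict[str, ConditionKey]:
    """Deterministic 8-nt barcodes (Hamming distance >= 2 apart) for the
    given condition keys."""
    pool = ["".join(c) for c in itertools.product(DNA_BASES, repeat=4)]
    barcodes = {}
    for i, key in enumerate(keys):
        quad = pool[(i * 5) % len(pool)]
        barcodes[quad + quad[::-1]] = key
    if len(barcodes) != len(keys):
        raise ValueError("too many conditions for the default barcode pool")
    return barcodes


@dataclass
class SimConfig:
    """Knobs of the simulator; ``seed`` is mandatory."""

    seed: int
    n_variants: int = 200
    loop_lengths: tuple[int, ...] = (5,)
    depth_dna: int = 200_000
    depth_rna: int = 200_000
    n_replicates: int = 2
    sigma_dna: float = 0.5        # lognormal SD of DNA copy weight
    f0_logit_mean: float = float(np.log(0.2 / 0.8))
    f0_logit_sd: float = 1.0
    p_switch: float = 0.3         # fraction of variants with real switching
    switch_beta: tuple[float, float] = (2.0, 2.0)
    error_rate: float = 0.0       # per-base substitution rate in reads
    # FACS-side knobs
    sigma_cell: float = 0.2       # per-cell log10 fluorescence SD
    n_cells: int = 2000           # cells per variant per sort
    n_bins: int = 6
    bin_edges: np.ndarray | None = None
    facs_reads_per_bin: int = 50_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ValueError("depths must be > 0")
        if self.n_bins < 2:
            raise ValueError("need >= 2 bins")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Per-variant truth table.

    Columns: f0, s, f1, w, true_ar, is_control. Index: loop sequence for
    library members, name for controls.
    """

    table: pd.DataFrame
    controls: tuple[ControlRibozyme, ...] = ()

    @property
    def variants(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "variant"
        out.to_csv(path, sep="\t")


def _sample_loops(rng: np.random.Generator, n: int,
                  lengths: Sequence[int]) -> list[str]:
    """n distinct loop sequences over the given lengths (enumerated in full
    when n covers the whole space)."""
    space = sum(4 ** l for l in lengths)
    if n >= space:
        loops = []
        for l in sorted(lengths):
            loops.extend("".join(c) for c in itertools.product(DNA_BASES, repeat=l))
        return loops
    # sample integer codes without replacement over the concatenated space
    codes = rng.choice(space, size=n, replace=False)
    offsets, loops = [], []
    start = 0
    for l in sorted(lengths):
        offsets.append((start, l))
        start += 4 ** l
    for code in codes:
        for off, l in reversed(offsets):
            if code >= off:
                idx = code - off
                loop = "".join(DNA_BASES[(idx >> (2 * k)) & 3] for k in range(l))
                loops.append(loop)
                break
    return loops


def simulate_ground_truth(config: SimConfig,
                          rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw a ground-truth library.

    f0 ~ logit-normal; switching strength s is a point mass at 0 with
    probability 1 - p_switch, else Beta; DNA copy weight w ~ lognormal(0,
    sigma_dna). Controls are appended with fixed f (non-switching) and
    weight 1.
    """
    rng = config.rng() if rng is None else rng
    loops = _sample_loops(rng, config.n_variants, config.loop_lengths)
    n = len(loops)
    f0 = 1.0 / (1.0 + np.exp(-rng.normal(config.f0_logit_mean,
                                         config.f0_logit_sd, size=n)))
    s = np.where(
        rng.random(n) < config.p_switch,
        rng.beta(*config.switch_beta, size=n),
        0.0,
    )
    if config.sigma_dna > 0:
        w = rng.lognormal(0.0, config.sigma_dna, size=n)
    else:
        w = np.ones(n)
    f1 = f0 + (1.0 - f0) * s

    controls = default_controls()
    rows = pd.DataFrame({
        "f0": f0, "s": s, "f1": f1, "w": w,
        "true_ar": f1 / f0, "is_control": False,
    }, index=pd.Index(loops, name="variant"))
    ctl_rows = pd.DataFrame({
        "f0": [f for _, f in controls],
        "s": 0.0,
        "f1": [f for _, f in controls],
        "w": 1.0,
        "true_ar": 1.0,
        "is_control": True,
    }, index=pd.Index([c.name for c, _ in controls], name="variant"))
    table = pd.concat([rows, ctl_rows])
    return GroundTruth(table=table, controls=tuple(c for c, _ in controls))


def expected_counts(gt: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Expected (non-sampled) DNA/RNA counts per condition; useful for
    analytic checks. Columns (assay, condition) without replicates."""
    t = gt.table
    w = t["w"].to_numpy()
    dna = w / w.sum() * config.depth_dna
    out = {}
    for condition, col in (("minus", "f0"), ("plus", "f1")):
        mass = w * t[col].to_numpy()
        out[("DNA", condition)] = dna
        out[("RNA", condition)] = mass / mass.sum() * config.depth_rna
    return pd.DataFrame(out, index=t.index)


def simulate_counts(gt: GroundTruth, config: SimConfig,
                    rng: np.random.Generator | None = None) -> CountTable:
    """Multinomial sequencing draws for both ligand conditions and all
    replicates. DNA probabilities follow copy weight; RNA probabilities
    follow copy weight times the condition's uncleaved fraction."""
    rng = config.rng() if rng is None else rng
    t = gt.table
    w = t["w"].to_numpy()
    cols = {}
    for condition, fcol in (("minus", "f0"), ("plus", "f1")):
        p_dna = w / w.sum()
        mass = w * t[fcol].to_numpy()
        p_rna = mass / mass.sum()
        for rep in range(1, config.n_replicates + 1):
            cols[("DNA", condition, rep)] = rng.multinomial(config.depth_dna, p_dna)
            cols[("RNA", condition, rep)] = rng.multinomial(config.depth_rna, p_rna)
    frame = pd.DataFrame(cols, index=t.index).sort_index(axis=1)
    frame.columns = frame.columns.set_names(("assay", "condition", "replicate"))
    controls = frozenset(c.name for c in gt.controls)
    return CountTable(frame, controls)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    if len(hits) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    counts: CountTable,
    template: LibraryTemplate,
    barcode_map: dict[str, ConditionKey],
    controls: Sequence[ControlRibozyme] = (),
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[str, str]]:
    """Emit (read_id, sequence) pairs realizing a count table.

    Each count produces one read: the condition's barcode followed by the
    variant's rendered architecture (or the control's sequence), with
    per-base substitution errors at ``error_rate``. At error_rate = 0 the
    reads round-trip exactly through demultiplex -> match -> count.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    key_to_barcode = {key: bc for bc, key in barcode_map.items()}
    control_seqs = {c.name: c.sequence for c in controls}
    i = 0
    for col in counts.counts.columns:
        barcode = key_to_barcode[col]
        for variant, count in counts.counts[col].items():
            if count <= 0:
                continue
            body = control_seqs.get(variant) or template.render(variant)
            read = barcode + body
            for _ in range(int(count)):
                yield f"read{i}", _mutate(read, error_rate, rng)
                i += 1


def write_fastq(reads: Iterator[tuple[str, str]], path) -> int:
    """Write simulated reads as FASTQ (constant quality); returns count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def auto_bin_edges(gt: GroundTruth, config: SimConfig,
                   condition: str = "minus") -> np.ndarray:
    """Default bin placement: open outer bins, the boundary between the two
    highest bins at the non-cleaving reference's true level (so the
    reference's cells split evenly across them), remaining edges spread
    evenly down to the dimmest variant."""
    fcol = "f0" if condition == "minus" else "f1"
    truth = np.log10(100.0 * gt.table[fcol].to_numpy())
    ref = np.log10(100.0 * 1.0)  # non-cleaving reference, f = 1
    lo = float(truth.min())
    if lo >= ref:
        lo = ref - 1.0
    interior = np.linspace(lo, ref, config.n_bins - 1)
    return np.concatenate([[-np.inf], interior, [np.inf]])


def simulate_facs(
    gt: GroundTruth,
    config: SimConfig,
    condition: str = "minus",
    rng: np.random.Generator | None = None,
) -> BinnedSortData:
    """Simulate one sort: per-cell log10 fluorescence ~ Normal(true level,
    sigma_cell), cells binned by the edges, per-bin reads multinomial over
    variants proportional to their cell counts."""
    rng = config.rng() if rng is None else rng
    fcol = "f0" if condition == "minus" else "f1"
    truth = np.log10(100.0 * gt.table[fcol].to_numpy())
    edges = (np.asarray(config.bin_edges, dtype=float)
             if config.bin_edges is not None
             else auto_bin_edges(gt, config, condition))
    n_bins = len(edges) - 1
    interior = edges[1:-1]

    n_var = len(truth)
    cell_counts = np.zeros((n_var, n_bins), dtype=float)
    for v in range(n_var):
        if config.sigma_cell > 0:
            samples = rng.normal(truth[v], config.sigma_cell, size=config.n_cells)
        else:
            samples = np.full(config.n_cells, truth[v])
        cell_counts[v] = np.bincount(
            np.searchsorted(interior, samples, side="right"),
            minlength=n_bins)

    cells_sorted = cell_counts.sum(axis=0)
    reads = np.zeros_like(cell_counts)
    for b in range(n_bins):
        total = cell_counts[:, b].sum()
        if total > 0:
            reads[:, b] = rng.multinomial(
                config.facs_reads_per_bin, cell_counts[:, b] / total)
    frame = pd.DataFrame(reads.astype(int), index=gt.table.index,
                         columns=[f"bin{i + 1}" for i in range(n_bins)])
    return BinnedSortData(bin_edges=edges, cells_sorted=cells_sorted, reads=frame)
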