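"""Sequence-function analysis of the randomized loop.

Operates on equal-length loop sequences paired with per-variant activity
values (log10 RD). Provides activity standardization and 14-bin
partitioning, per-position frequency/entropy (logo matrices), pairwise
mutual information, percentile contribution tensors, one-hot encoding, and
IUPAC motif subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library_model import as_dna

__all__ = [
    "BASE_ORDER",
    "IUPAC",
    "ActivityBinning",
    "MIMatrix",
    "PairwiseContribution",
    "standardize",
    "one_hot",
    "assign_activity_bins",
    "position_entropy",
    "mutual_information",
    "pairwise_percentile_contribution",
    "motif_subset",
]

#: One-hot / frequency-table base ordering (index 2 is U in RNA display).
BASE_ORDER = "ACTG"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

# 14-bin activity partition: bottom bin at z <= -2 SD, top bin at z >= +1 SD,
# 12 equal-width bins (0.25 SD) in between.
LOWER_CUT = -2.0
UPPER_CUT = 1.0
N_MID_BINS = 12


def _seq_matrix(seqs) -> np.ndarray:
    """Sequences as an (m, n) integer matrix over BASE_ORDER indices."""
    seqs = [as_dna(s) for s in seqs]
    if not seqs:
        raise ValueError("no sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must have equal length (align upstream)")
    try:
        return np.array([[_BASE_INDEX[b] for b in s] for s in seqs], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - as_dna already screens
        raise ValueError(f"ambiguous base {exc} not allowed") from exc


def standardize(values, ddof: int = 1) -> np.ndarray:
    """Z-scores: translated to mean 0 and scaled to SD 1 (sample SD by
    default; ``ddof=0`` for population SD)."""
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 2 or np.nanstd(x, ddof=ddof) == 0:
        raise ValueError("need >= 2 distinct finite values to standardize")
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=ddof)


def one_hot(seqs) -> np.ndarray:
    """Binary (m, 4n) encoding; per-position block ordering A, C, U/T, G."""
    mat = _seq_matrix(seqs)
    m, n = mat.shape
    out = np.zeros((m, 4 * n), dtype=np.int8)
    rows = np.repeat(np.arange(m), n)
    cols = (4 * np.tile(np.arange(n), m)) + mat.ravel()
    out[rows, cols] = 1
    return out


@dataclass
class ActivityBinning:
    """14-bin activity partition of standardized values."""

    z: np.ndarray
    bin_index: np.ndarray  # 1..14
    lower_cut: float = LOWER_CUT
    upper_cut: float = UPPER_CUT
    n_mid_bins: int = N_MID_BINS

    @property
    def n_bins(self) -> int:
        return self.n_mid_bins + 2


def assign_activity_bins(z) -> ActivityBinning:
    """Assign each z-score to one of 14 activity bins.

    Bin 1: z <= -2; bin 14: z >= +1; bins 2-13 are 12 equal left-closed
    intervals of width 0.25 over (-2, 1).
    """
    z = np.asarray(z, dtype=float)
    width = (UPPER_CUT - LOWER_CUT) / N_MID_BINS
    idx = 2 + np.floor((z - LOWER_CUT) / width).astype(int)
    idx = np.clip(idx, 1, N_MID_BINS + 2)
    idx[z <= LOWER_CUT] = 1
    idx[z >= UPPER_CUT] = N_MID_BINS + 2
    return ActivityBinning(z=z, bin_index=idx)


def _weighted_freqs(mat: np.ndarray, weights) -> np.ndarray:
    """(n, 4) per-position weighted base frequencies."""
    m, n = mat.shape
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
    freqs = np.zeros((n, 4))
    for k in range(4):
        freqs[:, k] = ((mat == k) * w[:, None]).sum(axis=0)
    return freqs / w.sum()


def position_entropy(seqs, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-position base frequencies (n, 4) and Shannon entropy in bits,
    with the 0*log(0) := 0 convention."""
    mat = _seq_matrix(seqs)
    freqs = _weighted_freqs(mat, weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return freqs, -terms.sum(axis=1)


@dataclass
class MIMatrix:
    """Pairwise mutual information (bits) between loop positions."""

    mi: np.ndarray           # (n, n); diagonal = per-position entropy
    p_joint: np.ndarray      # (n, n, 4, 4) weighted pair frequencies
    p_marg: np.ndarray       # (n, 4) weighted single-position frequencies

    @property
    def n_positions(self) -> int:
        return self.mi.shape[0]


def mutual_information(seqs, weights=None) -> MIMatrix:
    """Mutual information between every pair of positions.

    MI(i, j) = sum_{X,Y} P_ij(X,Y) log2( P_ij(X,Y) / (P_i(X) P_j(Y)) ),
    computed from (optionally weighted) observed frequencies. The diagonal
    holds the per-position entropy (MI of a position with itself).
    """
    mat = _seq_matrix(seqs)
    m, n = mat.shape
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
    wsum = w.sum()
    p_marg = _weighted_freqs(mat, weights)

    # joint via weighted one-hot cross products: (n,4) x (n,4) contractions
    onehot = np.zeros((m, n, 4))
    onehot[np.arange(m)[:, None], np.arange(n)[None, :], mat] = 1.0
    p_joint = np.einsum("m,mia,mjb->ijab", w, onehot, onehot) / wsum

    outer = p_marg[:, None, :, None] * p_marg[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p_joint > 0, p_joint * np.log2(p_joint / outer), 0.0)
    mi = terms.sum(axis=(2, 3))
    mi = np.maximum(mi, 0.0)
    return MIMatrix(mi=mi, p_joint=p_joint, p_marg=p_marg)


@dataclass
class PairwiseContribution:
    """q-th percentile of activity for sequences with base X at position i
    and base Y at position j; NaN where support < min_support."""

    percentiles: np.ndarray  # (n, n, 4, 4)
    support: np.ndarray      # (n, n, 4, 4) subset sizes
    q: float
    min_support: int

    def to_long(self) -> pd.DataFrame:
        """Long-format table (1-based positions, RNA display alphabet)."""
        n = self.percentiles.shape[0]
        rows = []
        display = "ACUG"
        for i in range(n):
            for j in range(n):
                for a in range(4):
                    for b in range(4):
                        rows.append({
                            "pos_i": i + 1, "pos_j": j + 1,
                            "base_i": display[a], "base_j": display[b],
                            "support": int(self.support[i, j, a, b]),
                            f"p{self.q:g}": self.percentiles[i, j, a, b],
                        })
        return pd.DataFrame(rows)


def pairwise_percentile_contribution(
    seqs, values, q: float = 5, min_support: int = 5
) -> PairwiseContribution:
    """Percentile-of-activity tensor over all (position, base) pairs.

    For each (i, j, X, Y) with at least ``min_support`` sequences carrying X
    at i and Y at j, the q-th percentile (linear interpolation between order
    statistics) of those sequences' values.
    """
    mat = _seq_matrix(seqs)
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(mat):
        raise ValueError("values must align with sequences")
    m, n = mat.shape
    perc = np.full((n, n, 4, 4), np.nan)
    supp = np.zeros((n, n, 4, 4), dtype=int)
    for i in range(n):
        for j in range(n):
            for a in range(4):
                sel_a = mat[:, i] == a
                for b in range(4):
                    sel = sel_a & (mat[:, j] == b)
                    k = int(sel.sum())
                    supp[i, j, a, b] = k
                    if k >= min_support:
                        perc[i, j, a, b] = np.percentile(vals[sel], q)
    return PairwiseContribution(percentiles=perc, support=supp,
                                q=q, min_support=min_support)


def motif_subset(seqs, motif: str, values=None) -> tuple[np.ndarray, dict]:
    """Mask of sequences matching an IUPAC motif, plus an activity summary.

    The motif must have the loop length; codes follow IUPAC (N = any base,
    R = purine, ...). When ``values`` (linear-scale RD) is given, the
    summary reports subset and library means and the fold reduction
    (library mean / subset mean).
    """
    motif = str(motif).upper().replace("U", "T")
    bad = [c for c in motif if c not in IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC codes: {bad}")
    seqs = [as_dna(s) for s in seqs]
    if any(len(s) != len(motif) for s in seqs):
        raise ValueError("motif length must equal loop length")
    allowed = [IUPAC[c] for c in motif]
    mask = np.array(
        [all(base in ok for base, ok in zip(s, allowed)) for s in seqs],
        dtype=bool)
    summary: dict = {"motif": motif, "n_total": len(seqs),
                     "n_match": int(mask.sum())}
    if values is not None:
        vals = np.asarray(values, dtype=float)
        library_mean = float(np.nanmean(vals))
        subset_mean = float(np.nanmean(vals[mask])) if mask.any() else float("nan")
        summary["library_mean"] = library_mean
        summary["subset_mean"] = subset_mean
        summary["fold_reduction"] = (
            library_mean / subset_mean if subset_mean and np.isfinite(subset_mean)
            else float("nan"))
    return mask, summary
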