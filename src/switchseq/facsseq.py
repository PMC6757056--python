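"""Sort-seq fluorescence reconstruction.

Cells carrying each library member are sorted into fluorescence bins and the
bins sequenced; a variant's read share of each bin estimates how many of its
cells landed there. The per-variant bin histogram is fit as an
interval-censored normal in log10 fluorescence-ratio space (maximum
multinomial likelihood, open-ended outer bins), then the fitted means are
mapped onto known control fluorescence levels and normalized so the
non-cleaving reference sits at 100 relative fluorescence units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .rnaseq_quant import DEFAULT_CONTROL, activation_ratio

__all__ = [
    "BinnedSortData",
    "FacsFit",
    "estimate_bin_cells",
    "estimate_cells",
    "bin_probabilities",
    "fit_binned_normal",
    "fit_all",
    "calibrate_and_normalize",
    "facs_activation_ratio",
]

SIGMA_FLOOR = 1e-3
MAX_ITER = 500
REL_TOL = 1e-8


@dataclass
class BinnedSortData:
    """Per-variant per-bin read counts plus the sort metadata.

    ``bin_edges`` are the B+1 increasing log10(fluorescence-ratio)
    boundaries (outer edges may be +-inf); ``cells_sorted`` is the number of
    cells collected per bin; ``reads`` is a variants x B count table;
    ``total_reads`` defaults to the per-bin column sums.
    """

    bin_edges: np.ndarray
    cells_sorted: np.ndarray
    reads: pd.DataFrame
    total_reads: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cells_sorted = np.asarray(self.cells_sorted, dtype=float)
        n_bins = len(self.bin_edges) - 1
        if n_bins < 2:
            raise ValueError("need at least 2 bins")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if (self.cells_sorted < 0).any():
            raise ValueError("cells_sorted must be >= 0")
        if self.reads.shape[1] != n_bins:
            raise ValueError("reads must have one column per bin")
        if self.total_reads is None:
            self.total_reads = self.reads.sum(axis=0).to_numpy(dtype=float)
        else:
            self.total_reads = np.asarray(self.total_reads, dtype=float)
            col_sums = self.reads.sum(axis=0).to_numpy(dtype=float)
            if (col_sums > self.total_reads + 1e-9).any():
                raise ValueError("per-variant reads exceed total_reads in a bin")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_tsv(self, reads_path, sidecar_path) -> None:
        reads = self.reads.copy()
        reads.columns = [f"bin{i + 1}" for i in range(self.n_bins)]
        reads.index.name = "variant"
        reads.to_csv(reads_path, sep="\t")
        meta = {
            "bin_edges": [float(e) for e in self.bin_edges],
            "cells_sorted": [float(c) for c in self.cells_sorted],
            "total_reads": [float(t) for t in self.total_reads],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_tsv(cls, reads_path, sidecar_path) -> "BinnedSortData":
        reads = pd.read_csv(reads_path, sep="\t", index_col="variant")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            bin_edges=np.array(meta["bin_edges"], dtype=float),
            cells_sorted=np.array(meta["cells_sorted"], dtype=float),
            reads=reads,
            total_reads=np.array(meta["total_reads"], dtype=float),
        )


@dataclass
class FacsFit:
    """Fitted log10 fluorescence distribution for one variant."""

    mu: float
    sigma: float
    rfu: float = float("nan")
    n_cells_est: float = 0.0
    converged: bool = True


def estimate_bin_cells(data: BinnedSortData, variant: str) -> np.ndarray:
    """Estimated cells of ``variant`` per bin: its read share of each bin
    times the cells sorted into that bin."""
    if variant not in data.reads.index:
        raise KeyError(f"variant {variant!r} not in sort data")
    reads = data.reads.loc[variant].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(data.total_reads > 0, reads / data.total_reads, 0.0)
    if ((reads > 0) & (data.total_reads <= 0)).any():
        raise ValueError("variant has reads in a bin with zero total reads")
    return share * data.cells_sorted


def estimate_cells(data: BinnedSortData) -> pd.DataFrame:
    """Vectorized :func:`estimate_bin_cells` over all variants."""
    reads = data.reads.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(data.total_reads > 0, reads / data.total_reads, 0.0)
    return pd.DataFrame(share * data.cells_sorted,
                        index=data.reads.index, columns=data.reads.columns)


def bin_probabilities(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Normal bin probabilities with the outer bins censored to +-inf."""
    edges = np.asarray(edges, dtype=float).copy()
    edges[0] = -np.inf
    edges[-1] = np.inf
    z = (edges - mu) / sigma
    cdf = np.where(np.isneginf(z), 0.0, np.where(np.isposinf(z), 1.0, ndtr(z)))
    return np.diff(cdf)


def _imputed_midpoints(edges: np.ndarray) -> np.ndarray:
    """Bin midpoints; open end bins imputed one bin-width beyond the edge."""
    edges = np.asarray(edges, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    finite = edges[np.isfinite(edges)]
    width = np.median(np.diff(finite)) if len(finite) >= 2 else 1.0
    if not np.isfinite(mids[0]):
        mids[0] = edges[1] - width
    if not np.isfinite(mids[-1]):
        mids[-1] = edges[-2] + width
    return mids


def fit_binned_normal(cells, edges) -> FacsFit:
    """Maximum-likelihood normal fit to interval-censored bin counts.

    Maximizes ``sum_b cells_b * log p_b(mu, sigma)`` where the p_b are
    censored-normal bin probabilities; sigma is bounded below at 1e-3.
    Initialized from the weighted mean/SD of (imputed) bin midpoints. When
    all mass sits in a single open end bin the likelihood is unbounded in
    mu, so the moment estimate is returned with ``converged=False``.
    """
    cells = np.asarray(cells, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be >= 0")
    total = cells.sum()
    if total <= 0:
        raise ValueError("no cells to fit")

    mids = _imputed_midpoints(edges)
    w = cells / total
    mu0 = float(np.dot(w, mids))
    sd0 = float(np.sqrt(np.dot(w, (mids - mu0) ** 2)))
    finite = edges[np.isfinite(edges)]
    width = float(np.median(np.diff(finite))) if len(finite) >= 2 else 1.0
    sd0 = max(sd0, 0.25 * width, SIGMA_FLOOR)

    occupied = np.flatnonzero(cells > 0)
    if len(occupied) == 1:
        b = occupied[0]
        open_low = b == 0 and not np.isfinite(edges[0])
        open_high = b == len(cells) - 1 and not np.isfinite(edges[-1])
        if open_low or open_high:
            return FacsFit(mu=mu0, sigma=sd0, n_cells_est=total, converged=False)

    def nll(theta):
        mu, sigma = theta
        p = bin_probabilities(edges, mu, sigma)
        p = np.clip(p, 1e-300, 1.0)
        return -np.dot(cells, np.log(p))

    res = minimize(
        nll, x0=np.array([mu0, sd0]), method="L-BFGS-B",
        bounds=[(None, None), (SIGMA_FLOOR, None)],
        options={"maxiter": MAX_ITER, "ftol": REL_TOL * 1e-2},
    )
    mu, sigma = float(res.x[0]), float(res.x[1])
    return FacsFit(mu=mu, sigma=sigma, n_cells_est=total, converged=bool(res.success))


def fit_all(data: BinnedSortData, min_cells: float = 1.0) -> pd.DataFrame:
    """Fit every variant in a BinnedSortData.

    Returns a DataFrame with columns mu, sigma, n_cells_est, converged;
    variants with fewer than ``min_cells`` estimated cells are skipped.
    """
    cells = estimate_cells(data)
    rows = {}
    for variant in cells.index:
        c = cells.loc[variant].to_numpy()
        if c.sum() < min_cells:
            continue
        fit = fit_binned_normal(c, data.bin_edges)
        rows[variant] = {
            "mu": fit.mu, "sigma": fit.sigma,
            "n_cells_est": fit.n_cells_est, "converged": fit.converged,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variant"
    return out


def calibrate_and_normalize(
    fits: pd.DataFrame,
    control_levels: dict[str, float],
    reference: str = DEFAULT_CONTROL,
) -> pd.DataFrame:
    """Map fitted mu values to relative fluorescence units via the controls.

    ``control_levels`` gives each control's known fluorescence on a linear
    scale (the reference, typically at 100). A least-squares line from
    fitted mu to known log10 fluorescence is fit over the controls; mapped
    values are exponentiated, divided by the mapped value of ``reference``,
    and scaled by 100. Adds an ``rfu`` column (reference = 100 by
    construction).
    """
    names = [n for n in control_levels if n in fits.index]
    if len(names) < 2:
        raise ValueError("need >= 2 fitted controls for calibration")
    if reference not in names:
        raise ValueError(f"reference control {reference!r} has no fit")
    mu_c = fits.loc[names, "mu"].to_numpy(dtype=float)
    known = np.log10([control_levels[n] for n in names])
    if np.ptp(mu_c) < 1e-12:
        raise ValueError("degenerate calibration: control mu values identical")
    slope, intercept = np.polyfit(mu_c, known, 1)

    mapped = slope * fits["mu"].to_numpy(dtype=float) + intercept
    ref_mapped = slope * float(fits.loc[reference, "mu"]) + intercept
    out = fits.copy()
    out["rfu"] = 10.0 ** (mapped - ref_mapped) * 100.0
    out.attrs["calibration"] = {"slope": float(slope), "intercept": float(intercept)}
    return out


def facs_activation_ratio(rfu_minus, rfu_plus):
    """Activation ratio of calibrated fluorescence values; see
    :func:`switchseq.rnaseq_quant.activation_ratio`."""
    return activation_ratio(rfu_minus, rfu_plus)
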