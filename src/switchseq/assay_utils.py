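"""Closed-form assay computations: gel densitometry, qPCR normalization,
flow-cytometry relative fluorescence with gating, and the one-site
equilibrium binding fit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GelBands",
    "QpcrSample",
    "FlowEventSet",
    "BindingFit",
    "DEFAULT_BFP_GATE",
    "fraction_cleaved",
    "fraction_uncleaved",
    "cleavage_fold_change",
    "qpcr_normalize",
    "flow_rfu",
    "binding_model",
    "fit_binding",
]

#: Transfection gate: only cells above this BFP level (10^2.7) are analyzed.
DEFAULT_BFP_GATE = 10 ** 2.7


@dataclass(frozen=True)
class GelBands:
    """Densitometry band intensities (arbitrary units) and fragment lengths
    (nt) for one lane."""

    i_cleaved: float
    i_uncleaved: float
    i_background: float
    length_cleaved: float
    length_uncleaved: float

    def __post_init__(self) -> None:
        if self.length_cleaved <= 0 or self.length_uncleaved <= 0:
            raise ValueError("fragment lengths must be > 0")
        if min(self.i_cleaved, self.i_uncleaved, self.i_background) < 0:
            raise ValueError("intensities must be >= 0")
        if self.i_background > min(self.i_cleaved, self.i_uncleaved):
            raise ValueError("background exceeds a band intensity")


def fraction_cleaved(bands: GelBands) -> float:
    """Fraction of transcripts cleaved, from length-normalized band signal.

    Stain signal scales with fragment length, so each
    background-subtracted intensity is divided by its fragment length:
    f = n_c / (n_c + n_u) with n_x = (I_x - I_bg) / length_x.
    """
    n_c = (bands.i_cleaved - bands.i_background) / bands.length_cleaved
    n_u = (bands.i_uncleaved - bands.i_background) / bands.length_uncleaved
    if n_c + n_u <= 0:
        raise ValueError("no signal in either band after background subtraction")
    return n_c / (n_c + n_u)


def fraction_uncleaved(bands: GelBands) -> float:
    """Complement of :func:`fraction_cleaved` (sums to 1 exactly)."""
    return 1.0 - fraction_cleaved(bands)


def cleavage_fold_change(f_with: float, f_without: float) -> tuple[float, float]:
    """Ligand-induced fold changes of the cleaved and uncleaved fractions:
    (f_with/f_without, (1 - f_with)/(1 - f_without))."""
    if f_without <= 0 or f_without >= 1:
        raise ValueError("fraction without ligand must be in (0, 1)")
    if not 0 <= f_with <= 1:
        raise ValueError("fractions must be in [0, 1]")
    return f_with / f_without, (1.0 - f_with) / (1.0 - f_without)


@dataclass(frozen=True)
class QpcrSample:
    """Reporter and internal-control transcript quantities for one sample."""

    mcherry_rna: float
    bfp_rna: float

    def __post_init__(self) -> None:
        if self.mcherry_rna < 0 or self.bfp_rna < 0:
            raise ValueError("quantities must be >= 0")


def qpcr_normalize(sample: QpcrSample, control: QpcrSample) -> float:
    """Reporter RNA per internal control, relative to the non-cleaving
    control sample and scaled to 100."""
    if control.mcherry_rna <= 0 or control.bfp_rna <= 0:
        raise ValueError("control quantities must be > 0")
    if sample.bfp_rna <= 0:
        raise ValueError("sample internal-control quantity must be > 0")
    sample_ratio = sample.mcherry_rna / sample.bfp_rna
    control_ratio = control.mcherry_rna / control.bfp_rna
    return sample_ratio / control_ratio * 100.0


@dataclass
class FlowEventSet:
    """Per-cell fluorescence intensities for one flow sample."""

    mcherry: np.ndarray
    bfp: np.ndarray
    gfp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mcherry = np.asarray(self.mcherry, dtype=float)
        self.bfp = np.asarray(self.bfp, dtype=float)
        if self.gfp is not None:
            self.gfp = np.asarray(self.gfp, dtype=float)
        arrays = [self.mcherry, self.bfp] + ([self.gfp] if self.gfp is not None else [])
        if len({len(a) for a in arrays}) != 1:
            raise ValueError("channel arrays must have equal length")
        if any((a < 0).any() for a in arrays):
            raise ValueError("intensities must be >= 0")

    def channel(self, name: str) -> np.ndarray:
        arr = getattr(self, name.lower(), None)
        if arr is None:
            raise ValueError(f"unknown or absent channel {name!r}")
        return arr


def _gated_ratio_mean(events: FlowEventSet, num: str, den: str,
                      gate: dict[str, float]) -> float:
    mask = np.ones(len(events.mcherry), dtype=bool)
    for channel, threshold in gate.items():
        mask &= events.channel(channel) > threshold
    if not mask.any():
        raise ValueError("no cells pass the gate")
    return float(np.mean(events.channel(num)[mask] / events.channel(den)[mask]))


def flow_rfu(
    events: FlowEventSet,
    control_events: FlowEventSet,
    gate: dict[str, float] | None = None,
    mode: str = "mcherry/bfp",
) -> float:
    """Relative fluorescence of a sample vs. the non-cleaving control.

    Gated per-cell ratio means (reporter / internal control), normalized to
    the control sample and scaled to 100. Default mode uses mCherry/BFP with
    the BFP transfection gate; ``mode="gfp/mcherry"`` for the green-reporter
    configuration (gate then defaults to mCherry).
    """
    num, den = [c.strip().lower() for c in mode.split("/")]
    if gate is None:
        gate = {den: DEFAULT_BFP_GATE}
    f_sample = _gated_ratio_mean(events, num, den, gate)
    f_control = _gated_ratio_mean(control_events, num, den, gate)
    return f_sample / f_control * 100.0


def binding_model(conc, rmax, kd, offset):
    """One-site equilibrium binding: R = [L] * Rmax / ([L] + KD) + offset."""
    conc = np.asarray(conc, dtype=float)
    return conc * rmax / (conc + kd) + offset


@dataclass
class BindingFit:
    rmax: float
    kd: float
    offset: float
    residual_norm: float
    identifiable: bool = True


def fit_binding(concentrations, responses) -> BindingFit:
    """Nonlinear least squares fit of the one-site binding model.

    KD is constrained positive. Initialization: Rmax = max(R) - min(R),
    KD = median([L]), offset = min(R). A flat response curve is flagged
    non-identifiable rather than fit.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if (conc < 0).any():
        raise ValueError("ligand concentrations must be >= 0")
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.ptp(resp) == 0:
        return BindingFit(rmax=0.0, kd=float("nan"), offset=float(resp[0]),
                          residual_norm=0.0, identifiable=False)
    p0 = [float(np.ptp(resp)), float(np.median(conc[conc > 0])), float(resp.min())]
    popt, _ = curve_fit(
        binding_model, conc, resp, p0=p0,
        bounds=([-np.inf, 1e-30, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000)
    resid = float(np.linalg.norm(binding_model(conc, *popt) - resp))
    return BindingFit(rmax=float(popt[0]), kd=float(popt[1]),
                      offset=float(popt[2]), residual_norm=resid)
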