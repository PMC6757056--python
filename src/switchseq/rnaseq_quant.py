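"""Normalized RNA/DNA activity, activation ratios, and switch significance.

The central quantity is the RD ratio: a variant's RNA/DNA read-count ratio
normalized to a non-cleaving control's ratio and scaled to 100, so a value
of 100 means "as much intact transcript as the non-cleaving reference".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .readcount import CountTable

__all__ = [
    "DEFAULT_CONTROL",
    "rd_normalize",
    "activation_ratio",
    "benjamini_hochberg",
    "switch_significance",
    "summarize_activity",
    "top_percentile_overlap",
    "read_activity_tsv",
    "write_activity_tsv",
]

DEFAULT_CONTROL = "sTRSVctl"

ACTIVITY_COLUMNS = [
    "rd_minus", "rd_plus", "log10_rd_minus", "log10_rd_plus", "ar", "p", "q",
]


def rd_normalize(
    table: CountTable,
    control: str | None = DEFAULT_CONTROL,
    fallback_top: int = 25,
) -> pd.DataFrame:
    """Per-variant normalized RNA/DNA activity, per condition and replicate.

    For each (condition, replicate) column::

        RD_i = (RNA_i / DNA_i) / normalizer * 100

    The normalizer is the control variant's RNA/DNA ratio; when the control
    row is absent (``control=None`` or missing from the table) it falls back
    to the mean RNA/DNA ratio of the ``fallback_top`` highest-ratio variants
    in that column.

    Variants with DNA = 0 in any column are dropped with a warning; RNA = 0
    gives RD = 0. Raises if the control is present with zero DNA anywhere,
    or the table is empty.

    Returns a DataFrame indexed by variant with (condition, replicate)
    columns; ``result.attrs["normalization"]`` records the mode used.
    """
    if table.counts.empty:
        raise ValueError("empty count table")
    dna = table.assay("DNA")
    rna = table.assay("RNA")
    rna = rna.reindex(columns=dna.columns)
    if rna.isna().any().any():
        raise ValueError("RNA and DNA columns do not align")

    have_control = control is not None and control in table.counts.index
    if have_control and (dna.loc[control] <= 0).any():
        raise ValueError(f"control {control!r} has zero DNA reads")

    zero_dna = (dna <= 0).any(axis=1)
    if zero_dna.any():
        warnings.warn(
            f"dropping {int(zero_dna.sum())} variant(s) with zero DNA reads",
            stacklevel=2)
        dna = dna.loc[~zero_dna]
        rna = rna.loc[~zero_dna]

    ratio = rna / dna
    if have_control:
        normalizer = ratio.loc[control]
        mode = f"control:{control}"
    else:
        k = min(fallback_top, len(ratio))
        normalizer = pd.Series(
            {col: ratio[col].nlargest(k).mean() for col in ratio.columns})
        mode = f"top-{fallback_top} fallback"
    if (normalizer <= 0).any():
        raise ValueError("normalizer is zero; no RNA signal to normalize to")

    rd = ratio.div(normalizer, axis=1) * 100.0
    rd.attrs["normalization"] = mode
    return rd


def activation_ratio(rd_minus, rd_plus):
    """Activation ratio AR = RD(+ligand) / RD(-ligand).

    Accepts scalars or aligned arrays/Series; RD(-ligand) = 0 yields NaN
    (undefined, reported as missing).
    """
    minus = np.asarray(rd_minus, dtype=float)
    plus = np.asarray(rd_plus, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.where(minus > 0, plus / minus, np.nan)
    if isinstance(rd_minus, pd.Series):
        return pd.Series(ar, index=rd_minus.index, name="ar")
    if ar.ndim == 0:
        return float(ar)
    return ar


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are ignored (and returned as NaN); the number of tests m is
    the number of finite p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[mask] = out
    return q


def switch_significance(
    log_rd_minus: pd.DataFrame,
    log_rd_plus: pd.DataFrame,
    sided: str = "two",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-variant unpaired t-test of log10 RD between ligand conditions,
    with BH correction across all tested variants.

    Rows are variants, columns replicates. ``sided="one"`` tests for an
    increase with ligand. Variants with any missing replicate (e.g. RD = 0
    excluded from the log scale) get NaN p/q. Zero variance in both groups
    with equal means gives p = 1 (no evidence), p = 0 if the means differ.

    Returns a DataFrame with columns ``p`` and ``q``.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    minus = log_rd_minus.to_numpy(dtype=float)
    plus = log_rd_plus.reindex(log_rd_minus.index).to_numpy(dtype=float)
    if minus.shape[1] < 2 or plus.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")

    complete = np.isfinite(minus).all(axis=1) & np.isfinite(plus).all(axis=1)
    p = np.full(len(minus), np.nan)
    if complete.any():
        alt = "greater" if sided == "one" else "two-sided"
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            # near-identical groups are handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                plus[complete], minus[complete], axis=1,
                equal_var=equal_var, alternative=alt)
        pv = np.asarray(res.pvalue, dtype=float)
        # degenerate zero-variance cases produce NaN in scipy
        sub_m, sub_p = minus[complete], plus[complete]
        zerovar = (sub_m.std(axis=1) == 0) & (sub_p.std(axis=1) == 0)
        same = np.isclose(sub_m.mean(axis=1), sub_p.mean(axis=1))
        pv = np.where(zerovar & same, 1.0, pv)
        if sided == "one":
            up = sub_p.mean(axis=1) > sub_m.mean(axis=1)
            pv = np.where(zerovar & ~same, np.where(up, 0.0, 1.0), pv)
        else:
            pv = np.where(zerovar & ~same, 0.0, pv)
        p[complete] = pv
    q = benjamini_hochberg(p)
    return pd.DataFrame({"p": p, "q": q}, index=log_rd_minus.index)


def summarize_activity(
    rd: pd.DataFrame,
    sided: str = "two",
    equal_var: bool = True,
    conditions: tuple[str, str] = ("minus", "plus"),
) -> pd.DataFrame:
    """Collapse a per-replicate RD table into the per-variant activity table.

    RD(+/-) are replicate means on the linear scale; the activation ratio is
    the ratio of those means; significance is tested on per-replicate log10
    RD (RD = 0 replicates excluded from the log scale).
    """
    c_minus, c_plus = conditions
    rd_minus_reps = rd[c_minus]
    rd_plus_reps = rd[c_plus]
    with np.errstate(divide="ignore"):
        log_minus = np.log10(rd_minus_reps.where(rd_minus_reps > 0))
        log_plus = np.log10(rd_plus_reps.where(rd_plus_reps > 0))
    rd_minus = rd_minus_reps.mean(axis=1)
    rd_plus = rd_plus_reps.mean(axis=1)
    out = pd.DataFrame(index=rd.index)
    out["rd_minus"] = rd_minus
    out["rd_plus"] = rd_plus
    with np.errstate(divide="ignore"):
        out["log10_rd_minus"] = np.log10(rd_minus.where(rd_minus > 0))
        out["log10_rd_plus"] = np.log10(rd_plus.where(rd_plus > 0))
    out["ar"] = activation_ratio(rd_minus, rd_plus)
    sig = switch_significance(log_minus, log_plus, sided=sided, equal_var=equal_var)
    out["p"] = sig["p"]
    out["q"] = sig["q"]
    out.attrs.update(rd.attrs)
    return out


def top_percentile_overlap(
    a: pd.Series,
    b: pd.Series,
    percentile: float = 95,
) -> tuple[set, set, set]:
    """Top-(100 - percentile)% variant sets of two rankings and their overlap.

    k = round((1 - percentile/100) * n) per table; ties broken by variant key
    (lexicographic) for determinism. Returns (set_a, set_b, intersection).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty ranking table")

    def top_set(s: pd.Series) -> set:
        k = int(round((1 - percentile / 100.0) * len(s)))
        ranked = s.sort_index().sort_values(ascending=False, kind="mergesort")
        return set(ranked.index[:k])

    sa, sb = top_set(a), top_set(b)
    return sa, sb, sa & sb


def write_activity_tsv(activity: pd.DataFrame, path) -> None:
    out = activity[ACTIVITY_COLUMNS].copy()
    out.index.name = "variant"
    out.to_csv(path, sep="\t")


def read_activity_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant")
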