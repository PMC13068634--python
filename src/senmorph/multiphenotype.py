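"""Integration of per-cell fluorescence readouts with morphometric states.

Covers the fluorescence-side phenotyping of the senescence morphometry
pipeline:

* FUCCI cell-cycle calls from red/green nuclear intensities (red-only G1,
  double-positive S, green-only G2/M).
* GFP-LC3 autophagosome puncta detection (thresholded connected components
  inside the cell mask) and the autophagic-cell rule: at least 5 clear puncta.
* CFSE dilution summaries per morphometric state (the dye halves with each
  division, so high retained signal marks non-proliferating enlarged cells).
* Median-circularity split into low-circularity (E-state proxy) and
  high-circularity (F-state proxy) groups with marker-level summaries, plus
  the mirrored split by marker level.
* Rank correlation of marker intensity against irregularity and area
  (marker distributions are heavy-tailed, so Spearman by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "CellCyclePhase",
    "classify_fucci",
    "classify_fucci_frame",
    "detect_puncta",
    "classify_autophagic",
    "percent_autophagic",
    "median_split_by_circularity",
    "cfse_by_state",
    "correlate_marker_morphometry",
    "background_cutoff",
    "state_phase_contingency",
]

logger = logging.getLogger(__name__)

MIN_AUTOPHAGIC_DOTS = 5  # "clear green dots" rule for calling a cell autophagic


class CellCyclePhase(str, Enum):
    G1 = "G1"
    S = "S"
    G2M = "G2M"
    UNCLASSIFIED = "unclassified"


def classify_fucci(
    red_mfi: float,
    green_mfi: float,
    red_cut: float,
    green_cut: float,
) -> CellCyclePhase:
    """FUCCI phase call: red-only G1, red+green S, green-only G2/M."""
    if red_mfi < 0 or green_mfi < 0:
        raise InputError("intensities must be non-negative")
    if red_cut <= 0 or green_cut <= 0:
        raise InputError("cutoffs must be positive")
    red, green = red_mfi > red_cut, green_mfi > green_cut
    if red and green:
        return CellCyclePhase.S
    if red:
        return CellCyclePhase.G1
    if green:
        return CellCyclePhase.G2M
    return CellCyclePhase.UNCLASSIFIED


def classify_fucci_frame(
    frame: pd.DataFrame,
    red_cut: float,
    green_cut: float,
    red_col: str = "mfi_fucci_red",
    green_col: str = "mfi_fucci_green",
) -> pd.DataFrame:
    """Vectorised FUCCI calls; appends a ``phase`` column."""
    frame = frame.copy()
    red = frame[red_col].to_numpy(dtype=float) > red_cut
    green = frame[green_col].to_numpy(dtype=float) > green_cut
    phase = np.full(len(frame), CellCyclePhase.UNCLASSIFIED.value, dtype=object)
    phase[red & ~green] = CellCyclePhase.G1.value
    phase[red & green] = CellCyclePhase.S.value
    phase[~red & green] = CellCyclePhase.G2M.value
    frame["phase"] = phase
    return frame


def background_cutoff(channel: np.ndarray, mask: np.ndarray, q: float = 97.5) -> float:
    """Default channel cutoff: the q-th percentile of background (mask == 0) pixels."""
    bg = np.asarray(channel, dtype=float)[np.asarray(mask) == 0]
    if bg.size == 0:
        raise InputError("no background pixels to estimate a cutoff")
    return float(np.percentile(bg, q))


def detect_puncta(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    intensity_threshold: float,
    min_spot_px: int = 3,
    max_spot_px: int = 400,
    pixel_size: float = 1.0,
) -> tuple[int, float]:
    """Count supra-threshold puncta (autophagosomes) inside one cell mask.

    Connected components of ``channel > intensity_threshold`` restricted to the
    mask, size-filtered to [min_spot_px, max_spot_px] pixels.  Returns
    ``(count, total area)``; total area is the summed component pixel count
    times ``pixel_size**2``.  An empty mask yields zero puncta.
    """
    channel = np.asarray(channel, dtype=float)
    cell_mask = np.asarray(cell_mask).astype(bool)
    if channel.shape != cell_mask.shape:
        raise InputError("channel and mask shapes differ")
    if not cell_mask.any():
        return 0, 0.0
    supra = (channel > intensity_threshold) & cell_mask
    labels, n = ndimage.label(supra)
    if n == 0:
        return 0, 0.0
    sizes = np.bincount(labels.ravel())[1:]
    keep = (sizes >= min_spot_px) & (sizes <= max_spot_px)
    count = int(keep.sum())
    total_area = float(sizes[keep].sum()) * pixel_size**2
    if keep.sum() and sizes[keep].max() > 3 * np.median(sizes[keep]):
        logger.info("puncta component much larger than median: possible merged spots")
    return count, total_area


def classify_autophagic(puncta_count: int, min_dots: int = MIN_AUTOPHAGIC_DOTS) -> bool:
    """Autophagic-cell call: at least ``min_dots`` clear puncta in the cytoplasm."""
    if puncta_count < 0:
        raise InputError("puncta_count must be >= 0")
    return puncta_count >= min_dots


def percent_autophagic(
    frame: pd.DataFrame,
    by: list[str] | tuple[str, ...] = ("condition", "timepoint"),
    puncta_col: str = "puncta_count",
    min_dots: int = MIN_AUTOPHAGIC_DOTS,
) -> pd.DataFrame:
    """Percentage of autophagic cells per group.

    Groups with no cells simply do not appear (missing, not 0%).
    """
    if puncta_col not in frame.columns:
        raise InputError(f"missing column {puncta_col!r}")
    by = [c for c in by if c in frame.columns]
    work = frame.copy()
    work["autophagic"] = work[puncta_col].apply(lambda c: classify_autophagic(int(c), min_dots))
    if not by:
        return pd.DataFrame([{
            "n": len(work),
            "n_autophagic": int(work["autophagic"].sum()),
            "percent_autophagic": 100.0 * work["autophagic"].mean(),
        }])
    rows = []
    for key, grp in work.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append({
            **dict(zip(by, key)),
            "n": len(grp),
            "n_autophagic": int(grp["autophagic"].sum()),
            "percent_autophagic": 100.0 * grp["autophagic"].mean(),
        })
    return pd.DataFrame(rows)


@dataclass
class SplitSummary:
    """Result of a median split: group assignment plus per-group marker summaries."""

    groups: pd.Series          # "low" / "high" per input row
    split_value: float
    summary: pd.DataFrame      # per-group mean/median/IQR of the split-against variable


def _group_summary(frame: pd.DataFrame, group_col: str, value_col: str) -> pd.DataFrame:
    rows = []
    for name, grp in frame.groupby(group_col, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        q1, q3 = (np.percentile(vals, [25, 75]) if len(vals) else (np.nan, np.nan))
        rows.append({
            group_col: name,
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "iqr_low": float(q1),
            "iqr_high": float(q3),
        })
    return pd.DataFrame(rows)


def median_split_by_circularity(
    frame: pd.DataFrame,
    marker_col: str,
    circularity_col: str = "circularity",
) -> tuple[SplitSummary, SplitSummary]:
    """Median-circularity split into E-state and F-state proxies.

    Cells below the median circularity form the low-circularity group (E-state
    proxy: elongated/extended); cells at or above it the high-circularity group
    (F-state proxy: flattened, round).  Ties at the median go to the high
    group.  Returns the circularity split (with marker summaries) and the
    mirrored split by marker level (with circularity summaries).
    """
    if len(frame) < 2:
        raise InputError("need >= 2 records for a median split")
    for col in (circularity_col, marker_col):
        if col not in frame.columns:
            raise InputError(f"missing column {col!r}")
    work = frame.copy()

    def split(col: str, against: str) -> SplitSummary:
        values = work[col].to_numpy(dtype=float)
        med = float(np.median(values))
        groups = pd.Series(np.where(values < med, "low", "high"), index=work.index, name=f"{col}_group")
        if (groups == "high").all():
            warnings.warn(f"all {col} values tied at the median; single group", stacklevel=3)
        tmp = work.assign(**{groups.name: groups})
        return SplitSummary(groups=groups, split_value=med,
                            summary=_group_summary(tmp, groups.name, against))

    by_circ = split(circularity_col, marker_col)
    by_marker = split(marker_col, circularity_col)
    return by_circ, by_marker


def cfse_by_state(
    frame: pd.DataFrame,
    cfse_col: str = "sum_cfse",
    state_col: str = "condensed_state",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median +- IQR of CFSE signal per morphometric state, with pairwise tests.

    Pairwise comparisons use the Mann-Whitney U test (CFSE distributions are
    skewed).  With a single state present, comparisons are skipped but the
    summary is still emitted.
    """
    for col in (cfse_col, state_col):
        if col not in frame.columns:
            raise InputError(f"missing column {col!r}")
    summary = _group_summary(frame, state_col, cfse_col)
    states = summary[state_col].tolist()
    rows = []
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            va = frame.loc[frame[state_col] == a, cfse_col].to_numpy(dtype=float)
            vb = frame.loc[frame[state_col] == b, cfse_col].to_numpy(dtype=float)
            if len(va) == 0 or len(vb) == 0:
                continue
            stat, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "test": "mann-whitney",
                         "statistic": float(stat), "p": float(p)})
    return summary, pd.DataFrame(rows, columns=["group_a", "group_b", "test", "statistic", "p"])


def correlate_marker_morphometry(
    frame: pd.DataFrame,
    marker_col: str,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate a marker against irregularity and area.

    Spearman rank correlation by default; Pearson available via ``method``.
    Requires >= 10 paired observations; constant inputs are undefined.
    """
    if marker_col not in frame.columns:
        raise InputError(f"missing column {marker_col!r}")
    if len(frame) < 10:
        raise InputError("need >= 10 paired observations")
    marker = frame[marker_col].to_numpy(dtype=float)
    if np.ptp(marker) == 0:
        raise UndefinedStatisticError(f"{marker_col} is constant")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for target in ("irregularity", "area"):
        other = frame[target].to_numpy(dtype=float)
        if np.ptp(other) == 0:
            raise UndefinedStatisticError(f"{target} is constant")
        res = corr(marker, other)
        coef, p = float(res.statistic), float(res.pvalue)
        rows.append({"marker": marker_col, "against": target, "method": method,
                     "coefficient": coef, "p": p,
                     "sign": "positive" if coef > 0 else ("negative" if coef < 0 else "zero")})
    return pd.DataFrame(rows)


def state_phase_contingency(
    frame: pd.DataFrame,
    state_col: str = "condensed_state",
    phase_col: str = "phase",
) -> pd.DataFrame:
    """State x cell-cycle-phase contingency table (input for a chi-square test)."""
    for col in (state_col, phase_col):
        if col not in frame.columns:
            raise InputError(f"missing column {col!r}")
    return pd.crosstab(frame[state_col], frame[phase_col])
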