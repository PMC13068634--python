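"""Control-calibrated morphospace gating (NMA for nuclei, CellMorph for cells).

A *normal ellipse* is fitted to the control population in (area, irregularity)
space: its center is the control mean, its shape the control sample covariance,
and its Mahalanobis radius is grown until it empirically contains 90-95% of the
control objects.  Horizontal (area) thresholds are the upper and lower area
extremes attained on the ellipse boundary; a vertical (irregularity) threshold
separates regular from irregular objects, placed either manually — mirroring
the flow-cytometry-style user gating the method derives from — or automatically
at the deepest kernel-density valley of irregularity among objects outside the
ellipse.

The fitted :class:`GatingModel` is frozen once and applied unchanged to every
condition, so class percentages are comparable across treatments.  Classes:

=====  ========================================================
N      normal (inside the ellipse, or in the mid-area band with
       low irregularity)
LR     large regular  — area above the upper threshold, low
       irregularity; the flattened senescent F-state at cell level
LI     large irregular — area above the upper threshold, high
       irregularity; the extension-rich senescent E-state
I      irregular (mid-area band, high irregularity)
SR     small regular  (area below the lower threshold)
SI     small irregular
=====  ========================================================

Objects whose area exceeds the control mean + k*SD (k = 6 by default) carry an
additional ``very_large`` flag, subdividing the LR/LI classes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateControlError,
    InputError,
    InsufficientControlError,
)
from .morphometry import Compartment, MorphoRecord, records_to_frame

__all__ = [
    "ClassLabel",
    "MorphoClass",
    "NormalEllipse",
    "GatingModel",
    "fit_normal_ellipse",
    "place_thresholds",
    "fit_gating_model",
    "classify_record",
    "classify_frame",
    "summarize_quadrants",
]

Records = Union[Sequence[MorphoRecord], pd.DataFrame]

MIN_CONTROL_RECORDS = 50
CONTAINMENT_LOW = 0.90
CONTAINMENT_HIGH = 0.95


class ClassLabel(str, Enum):
    N = "N"
    LR = "LR"
    LI = "LI"
    I = "I"  # noqa: E741 - the field's own class symbol
    SR = "SR"
    SI = "SI"


@dataclass(frozen=True)
class MorphoClass:
    value: ClassLabel
    very_large: bool = False

    def __post_init__(self):
        if self.very_large and self.value not in (ClassLabel.LR, ClassLabel.LI):
            raise InputError("very_large applies only to LR/LI classes")


@dataclass(frozen=True)
class NormalEllipse:
    center: tuple[float, float]           # (area, irregularity)
    covariance: tuple[tuple[float, float], tuple[float, float]]
    radius: float                          # Mahalanobis radius
    containment_achieved: float

    def mahalanobis(self, area, irregularity) -> np.ndarray:
        cov = np.asarray(self.covariance)
        inv = np.linalg.inv(cov)
        d = np.column_stack([
            np.asarray(area, dtype=float) - self.center[0],
            np.asarray(irregularity, dtype=float) - self.center[1],
        ])
        return np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))

    def contains(self, area, irregularity) -> np.ndarray:
        return self.mahalanobis(area, irregularity) <= self.radius

    def boundary(self, n: int = 256) -> np.ndarray:
        """Points on the ellipse boundary, for plotting and area extremes."""
        cov = np.asarray(self.covariance)
        L = np.linalg.cholesky(cov)
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        circ = np.column_stack([np.cos(t), np.sin(t)])
        return self.radius * circ @ L.T + np.asarray(self.center)


@dataclass
class GatingModel:
    compartment: Compartment
    ellipse: NormalEllipse
    area_high: float
    area_low: float
    irr_threshold: float
    control_area_mean: float
    control_area_sd: float
    very_large_k: float = 6.0
    irr_threshold_source: str = "auto"
    n_control: int = 0

    @property
    def containment_achieved(self) -> float:
        return self.ellipse.containment_achieved

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["compartment"] = self.compartment.value
        from . import __version__
        payload["software_version"] = __version__
        payload["fitted_at"] = datetime.now(timezone.utc).isoformat()
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GatingModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        payload.pop("software_version", None)
        payload.pop("fitted_at", None)
        ell = payload.pop("ellipse")
        ell["center"] = tuple(ell["center"])
        ell["covariance"] = tuple(tuple(row) for row in ell["covariance"])
        return cls(
            compartment=Compartment(payload.pop("compartment")),
            ellipse=NormalEllipse(**ell),
            **payload,
        )


def _as_frame(records: Records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def fit_normal_ellipse(
    control_records: Records,
    containment_target: float = 0.925,
) -> NormalEllipse:
    """Fit the control normal ellipse in (area, irregularity) space.

    The Mahalanobis radius is chosen empirically (not from a parametric
    chi-square quantile, since control distributions need not be Gaussian): the
    smallest radius containing at least 90% of controls, grown toward
    ``containment_target`` but capped so containment stays <= 95%.
    """
    frame = _as_frame(control_records)
    n = len(frame)
    if n < MIN_CONTROL_RECORDS:
        raise InsufficientControlError(
            f"need >= {MIN_CONTROL_RECORDS} control records, got {n}"
        )
    if "compartment" in frame.columns and frame["compartment"].nunique() > 1:
        raise InputError("control records mix compartments")
    xy = frame[["area", "irregularity"]].to_numpy(dtype=float)
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 1e-12 * max(
        1.0, float(np.trace(cov)) ** 2
    ):
        raise DegenerateControlError(
            "control covariance is singular (constant area or irregularity)"
        )
    inv = np.linalg.inv(cov)
    d = xy - center
    dist = np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))
    dist_sorted = np.sort(dist)
    target = min(max(containment_target, CONTAINMENT_LOW), CONTAINMENT_HIGH)
    k = int(math.floor(target * n))
    k = max(k, int(math.ceil(CONTAINMENT_LOW * n)))
    # shrink if ties at the radius push empirical containment past the cap
    while k > 1:
        radius = dist_sorted[k - 1]
        contained = float(np.mean(dist <= radius))
        if contained <= CONTAINMENT_HIGH or k <= int(math.ceil(CONTAINMENT_LOW * n)):
            break
        k -= 1
    return NormalEllipse(
        center=(float(center[0]), float(center[1])),
        covariance=tuple(tuple(float(v) for v in row) for row in cov),
        radius=float(radius),
        containment_achieved=contained,
    )


def _kde_valley(values: np.ndarray) -> Optional[float]:
    """Deepest kernel-density valley between the two dominant irregularity modes.

    Irregularity is strictly positive and heavy-tailed, so the density is
    estimated on a log scale; the threshold is the deepest local minimum lying
    between the two tallest modes (minima beyond the outer modes are spurious
    tails, not subpopulation boundaries).  Returns None when the density has no
    interior valley.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10 or np.ptp(values) <= 0:
        return None
    eps = max(1e-6, 1e-3 * float(np.median(np.abs(values))))
    logv = np.log(values + eps)
    try:
        kde = stats.gaussian_kde(logv)
    except np.linalg.LinAlgError:
        return None
    grid = np.linspace(logv.min(), logv.max(), 512)
    dens = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    is_min = (dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    maxima = interior[is_max]
    minima = interior[is_min]
    if len(maxima) < 2 or len(minima) == 0:
        return None
    top_two = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    between = minima[(minima > top_two[0]) & (minima < top_two[1])]
    if len(between) == 0:
        return None
    deepest = between[np.argmin(dens[between])]
    return float(np.exp(grid[deepest]) - eps)


def place_thresholds(
    control_records: Records,
    ellipse: NormalEllipse,
    irr_threshold: Optional[float] = None,
    *,
    all_records: Optional[Records] = None,
    very_large_k: float = 6.0,
    compartment: Optional[Compartment | str] = None,
) -> GatingModel:
    """Place the area and irregularity thresholds and assemble the model.

    Area thresholds are the max/min area attained on the ellipse boundary.
    The irregularity threshold is the manual value if supplied; otherwise it is
    placed automatically at the deepest kernel-density valley of irregularity
    among records outside the ellipse (``all_records`` if given, else the
    controls), falling back to the control 97.5th irregularity percentile when
    no interior valley exists.  The chosen threshold and its provenance are
    recorded on the model.
    """
    frame = _as_frame(control_records)
    if compartment is None:
        compartment = Compartment(frame["compartment"].iloc[0]) if "compartment" in frame else Compartment.CELL
    # area extent of the Mahalanobis ellipse: center +- radius * sd(area)
    sd_area = math.sqrt(ellipse.covariance[0][0])
    area_high = ellipse.center[0] + ellipse.radius * sd_area
    area_low = ellipse.center[0] - ellipse.radius * sd_area
    source = "manual"
    if irr_threshold is None:
        pool = _as_frame(all_records) if all_records is not None else frame
        outside = pool.loc[
            ~ellipse.contains(pool["area"], pool["irregularity"]), "irregularity"
        ].to_numpy(dtype=float)
        valley = _kde_valley(outside)
        if valley is not None:
            irr_threshold, source = valley, "kde-valley"
        else:
            irr_threshold = float(np.percentile(frame["irregularity"], 97.5))
            source = "control-percentile"
    else:
        max_center_irr = ellipse.center[1] + ellipse.radius * math.sqrt(
            ellipse.covariance[1][1]
        )
        if irr_threshold <= max_center_irr:
            import warnings

            warnings.warn(
                "manual irregularity threshold lies inside the normal region",
                stacklevel=2,
            )
    areas = frame["area"].to_numpy(dtype=float)
    return GatingModel(
        compartment=Compartment(compartment),
        ellipse=ellipse,
        area_high=float(area_high),
        area_low=float(area_low),
        irr_threshold=float(irr_threshold),
        control_area_mean=float(areas.mean()),
        control_area_sd=float(areas.std(ddof=1)),
        very_large_k=very_large_k,
        irr_threshold_source=source,
        n_control=len(frame),
    )


def fit_gating_model(
    control_records: Records,
    *,
    containment_target: float = 0.925,
    irr_threshold: Optional[float] = None,
    all_records: Optional[Records] = None,
    very_large_k: float = 6.0,
) -> GatingModel:
    """Fit ellipse and thresholds in one call (the usual entry point)."""
    ellipse = fit_normal_ellipse(control_records, containment_target)
    return place_thresholds(
        control_records,
        ellipse,
        irr_threshold,
        all_records=all_records,
        very_large_k=very_large_k,
    )


def _classify_xy(area: float, irr: float, model: GatingModel) -> MorphoClass:
    ell = model.ellipse
    very_large = area > model.control_area_mean + model.very_large_k * model.control_area_sd
    if float(ell.mahalanobis([area], [irr])[0]) <= ell.radius:
        return MorphoClass(ClassLabel.N)
    irregular = irr >= model.irr_threshold
    if area > model.area_high:
        label = ClassLabel.LI if irregular else ClassLabel.LR
        return MorphoClass(label, very_large=very_large)
    if area < model.area_low:
        return MorphoClass(ClassLabel.SI if irregular else ClassLabel.SR)
    return MorphoClass(ClassLabel.I if irregular else ClassLabel.N)


def classify_record(record: MorphoRecord | pd.Series, model: GatingModel) -> MorphoClass:
    """Classify one object; ties at exact thresholds resolve to the less extreme class."""
    if isinstance(record, pd.Series):
        comp = Compartment(record["compartment"]) if "compartment" in record else model.compartment
        area, irr = float(record["area"]), float(record["irregularity"])
    else:
        comp, area, irr = record.compartment, record.area, record.irregularity
    if comp != model.compartment:
        raise InputError(
            f"record compartment {comp.value!r} != model compartment {model.compartment.value!r}"
        )
    return _classify_xy(area, irr, model)


def classify_frame(frame: Records, model: GatingModel) -> pd.DataFrame:
    """Vectorised classification; appends ``morpho_class`` and ``very_large`` columns."""
    frame = _as_frame(frame).copy()
    if "compartment" in frame.columns:
        bad = frame["compartment"].ne(model.compartment.value)
        if bad.any():
            raise InputError("records do not match model compartment")
    area = frame["area"].to_numpy(dtype=float)
    irr = frame["irregularity"].to_numpy(dtype=float)
    inside = model.ellipse.contains(area, irr)
    irregular = irr >= model.irr_threshold
    label = np.where(irregular, ClassLabel.I.value, ClassLabel.N.value)
    label = np.where(area > model.area_high,
                     np.where(irregular, ClassLabel.LI.value, ClassLabel.LR.value), label)
    label = np.where(area < model.area_low,
                     np.where(irregular, ClassLabel.SI.value, ClassLabel.SR.value), label)
    label = np.where(inside, ClassLabel.N.value, label)
    very_large = (
        area > model.control_area_mean + model.very_large_k * model.control_area_sd
    ) & np.isin(label, [ClassLabel.LR.value, ClassLabel.LI.value])
    frame["morpho_class"] = label
    frame["very_large"] = very_large
    return frame


def summarize_quadrants(records: Records, model: GatingModel) -> pd.DataFrame:
    """Per-condition, per-timepoint class counts, percentages and class means.

    Returns one row per (condition, timepoint, class) with ``count``,
    ``percent`` (summing to 100 within each condition x timepoint), and the
    class mean area and irregularity.  Classes absent from a group appear with
    zero count.
    """
    frame = _as_frame(records)
    if len(frame) == 0:
        raise InputError("no records to summarize")
    if "morpho_class" not in frame.columns:
        frame = classify_frame(frame, model)
    for col, default in (("condition", ""), ("timepoint", 0.0)):
        if col not in frame.columns:
            frame[col] = default
    rows = []
    for (cond, tp), grp in frame.groupby(["condition", "timepoint"], sort=True):
        total = len(grp)
        for label in ClassLabel:
            sub = grp[grp["morpho_class"] == label.value]
            rows.append({
                "condition": cond,
                "timepoint": tp,
                "morpho_class": label.value,
                "count": len(sub),
                "percent": 100.0 * len(sub) / total,
                "mean_area": float(sub["area"].mean()) if len(sub) else np.nan,
                "mean_irregularity": float(sub["irregularity"].mean()) if len(sub) else np.nan,
                "n_very_large": int(sub["very_large"].sum()) if "very_large" in sub else 0,
            })
    return pd.DataFrame(rows)
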