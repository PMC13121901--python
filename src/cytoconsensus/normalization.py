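"""Bead-anchored two-point batch normalization.

Single-stain compensation beads produce one sharp negative and one
sharp positive peak per channel and are acquired on every day of a
study. Assuming the number of bound antibodies per bead does not change
between days, measured intensity is (locally) affine in antibody count,
so the two bead peaks anchor a unique affine map between two days'
intensity scales:

    I_ref = (I_ref_H - I_ref_L) / (I_src_H - I_src_L) * (I_src - I_src_L) + I_ref_L

where L/H are the chosen statistic (median by default) of the lower and
higher bead peak on each day. The slope ratio is reported per channel:
when it exceeds 1 the normalized day's spread is amplified, which
inflates low-signal distributions and is the method's main caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import (
    AmbiguousPeaksError,
    DegenerateControlError,
    ParameterError,
    TooFewEventsError,
    UnimodalError,
)
from .io_model import EventMatrix, SampleType, StudySet


@dataclass(frozen=True)
class PeakPair:
    """Lower/higher bead-peak statistics (linear scale) for one channel/day."""

    low: float
    high: float
    statistic: str = "median"

    def __post_init__(self):
        if self.statistic not in ("median", "mean"):
            raise ParameterError(f"unknown statistic {self.statistic!r}")
        if not self.high > self.low:
            raise ParameterError(f"peak pair requires high > low, got {self}")


@dataclass(frozen=True)
class TwoPointNormModel:
    """Affine map sending the source day's bead anchors onto the reference day's.

    ``day1`` is the reference (target) pair, ``day2`` the source pair;
    applying the model to ``day2.low``/``day2.high`` returns
    ``day1.low``/``day1.high`` exactly.
    """

    day1: PeakPair
    day2: PeakPair
    channel: str

    @property
    def slope_ratio(self) -> float:
        return (self.day1.high - self.day1.low) / (self.day2.high - self.day2.low)

    @property
    def is_identity(self) -> bool:
        return self.day1 == self.day2


def detect_control_peaks(
    values: np.ndarray,
    statistic: str = "median",
    cofactor: float = 150.0,
    min_separation: float = 0.5,
    grid_size: int = 512,
) -> PeakPair:
    """Find the two dominant modes of a bead channel and summarize them.

    A Gaussian KDE (Silverman bandwidth) is computed on the arcsinh
    scale; the two highest local maxima are taken as the negative and
    positive peaks, events are split at the deepest density valley
    between them, and the chosen statistic of each side is returned on
    the linear scale.

    ``min_separation`` is the minimum distance between the two modes in
    arcsinh units; closer modes raise :class:`AmbiguousPeaksError`.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 200:
        raise TooFewEventsError(
            f"peak detection needs >= 200 events, got {values.size}")
    t = np.arcsinh(values / cofactor)
    if np.ptp(t) == 0:
        raise UnimodalError("all events identical; no two peaks to detect")
    kde = gaussian_kde(t, bw_method="silverman")
    grid = np.linspace(t.min(), t.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    modes = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        modes = np.r_[0, modes]
    if dens[-1] > dens[-2]:
        modes = np.r_[modes, grid_size - 1]
    if modes.size < 2:
        raise UnimodalError("fewer than two density modes in bead channel")
    top2 = modes[np.argsort(dens[modes])[-2:]]
    lo_m, hi_m = int(top2.min()), int(top2.max())
    if grid[hi_m] - grid[lo_m] < min_separation:
        raise AmbiguousPeaksError(
            f"modes separated by {grid[hi_m] - grid[lo_m]:.3f} < "
            f"{min_separation} arcsinh units")
    valley = lo_m + int(np.argmin(dens[lo_m : hi_m + 1]))
    threshold = grid[valley]
    lower, upper = values[t <= threshold], values[t > threshold]
    stat = np.median if statistic == "median" else np.mean
    return PeakPair(low=float(stat(lower)), high=float(stat(upper)),
                    statistic=statistic)


def fit_two_point_norm(day1: PeakPair, day2: PeakPair, channel: str) -> TwoPointNormModel:
    """Fit the affine map taking day2's anchors to day1's."""
    if day2.high == day2.low:
        raise DegenerateControlError("source-day peaks coincide")
    return TwoPointNormModel(day1=day1, day2=day2, channel=channel)


def apply_norm(m: TwoPointNormModel, values: np.ndarray) -> np.ndarray:
    """Elementwise affine map; anchors map exactly, order is preserved."""
    values = np.asarray(values, dtype=np.float64)
    return m.slope_ratio * (values - m.day2.low) + m.day1.low


def normalize_study(
    s: StudySet,
    statistic: str = "median",
    reference_day: int | None = None,
    identity_rel_tol: float = 0.01,
    cofactor: float = 150.0,
) -> tuple[StudySet, pd.DataFrame]:
    """Normalize every non-reference day of a study onto a reference day.

    Per channel, bead peaks are detected in that channel's single-stain
    sample on each day and a two-point model maps the source day onto
    the reference. By default the reference is the day with the higher
    positive-peak signal (averaged over channels), so lower-signal days
    are amplified onto it. Channels whose anchors already agree to
    within ``identity_rel_tol`` (relative) get the identity model, to
    avoid amplifying noise where there is no batch effect.

    All samples of a source day — beads, unlabeled, and labeled cells —
    are normalized uniformly. Returns the normalized study and a
    per-(day, channel) model report with anchors and slope ratios.
    """
    days = s.days
    if len(days) < 2:
        return s, pd.DataFrame()
    panel = s.panel

    pairs: dict[tuple[int, str], PeakPair] = {}
    for day in days:
        for ch in panel.channels:
            beads = s.select(SampleType.bead_single_stain, day=day, stain_channel=ch)
            if not beads:
                raise ParameterError(f"no single-stain bead sample for {ch} on day {day}")
            pairs[(day, ch)] = detect_control_peaks(
                beads[0][1].channel(ch), statistic=statistic, cofactor=cofactor)

    if reference_day is None:
        mean_high = {d: np.mean([pairs[(d, ch)].high for ch in panel.channels])
                     for d in days}
        reference_day = max(days, key=lambda d: mean_high[d])

    models: dict[tuple[int, str], TwoPointNormModel] = {}
    rows = []
    for day in days:
        for ch in panel.channels:
            ref, src = pairs[(reference_day, ch)], pairs[(day, ch)]
            rel = max(abs(src.high - ref.high) / abs(ref.high),
                      abs(src.low - ref.low) / max(abs(ref.low), 1e-12))
            if day == reference_day or rel < identity_rel_tol:
                model = fit_two_point_norm(ref, ref, ch)
            else:
                model = fit_two_point_norm(ref, src, ch)
            models[(day, ch)] = model
            rows.append({
                "day": day, "channel": ch, "reference_day": reference_day,
                "low_anchor": src.low, "high_anchor": src.high,
                "ref_low": ref.low, "ref_high": ref.high,
                "slope_ratio": model.slope_ratio,
                "identity": model.is_identity,
            })

    def _norm(meta, m: EventMatrix) -> EventMatrix:
        out = m.values.copy()
        for j, ch in enumerate(panel.channels):
            model = models[(meta.day, ch)]
            if not model.is_identity:
                out[:, j] = apply_norm(model, out[:, j])
        return EventMatrix(out, m.panel, m.scale)

    normalized = s.map_values(_norm)
    if hasattr(s, "truth"):
        normalized.truth = s.truth
    return normalized, pd.DataFrame(rows)
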