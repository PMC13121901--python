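"""Traditional layered (sequential) gating and its variation study.

Five markers need at least three gating layers: (1) a CD45 histogram
gate to remove hematopoietic cells, (2) CD31/PDPN quadrants of the
CD45-negative events separating the four main stromal types
(double-negative -> PvC_DN, CD31+PDPN- -> BEC, CD31+PDPN+ -> LEC,
CD31-PDPN+ -> FRC), and (3) ICAM-1/VCAM-1 quadrants within the FRC and
PvC_DN populations. Negative gates are placed so that a chosen fraction
(the *retention*) of unlabeled-control events stays inside them; the
variation study reruns the whole cascade under several retention
criteria and reports the coefficient of variation of population counts,
the robustness baseline against which consensus gating is compared.
Gate-placement variation compounds across layers, which is the point
the study quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_model import EventMatrix, SampleType, StudySet

QUADRANT_LABELS = ("neg", "x_pos", "y_pos", "double_pos")

#: layer-2 quadrant -> population name (x = CD31, y = PDPN)
LAYER2_POPULATIONS = {
    "neg": "PvC_DN",
    "x_pos": "BEC",
    "double_pos": "LEC",
    "y_pos": "FRC",
}


@dataclass(frozen=True)
class GatingCriteria:
    """One gate-placement strategy.

    ``retention`` is the fraction of unlabeled-control events that must
    remain inside every negative gate (0.995, 0.999 and 1.0 are the
    conventional variants). ``margin`` optionally perturbs every cutoff
    multiplicatively (cutoff * (1 + margin)), emulating a user dragging
    gates outward/inward.
    """

    retention: float = 0.999
    boundary_style: str = "axis_aligned"
    margin: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.retention <= 1.0:
            raise ParameterError("retention must be in (0, 1]")
        if self.boundary_style not in ("axis_aligned", "oblique"):
            raise ParameterError(f"unknown boundary_style {self.boundary_style!r}")


@dataclass(frozen=True)
class GateThreshold:
    channel: str
    cutoff: float
    retention_used: float


@dataclass
class GatingResult:
    """Output of one sequential-gating run."""

    labels: pd.DataFrame  # per labeled-cell event: sample_id/day/passage/layer1/layer2/terminal
    thresholds: dict[str, GateThreshold]
    counts: pd.Series  # per terminal population
    layer_counts: dict[int, pd.Series]


def quantile_gate(
    neg_values: np.ndarray | list[np.ndarray],
    retention: float,
    channel: str = "",
) -> GateThreshold:
    """Smallest cutoff retaining at least ``retention`` of every control.

    With several control samples the constraint must hold for each, so
    the largest per-sample cutoff wins.
    """
    if not 0.0 < retention <= 1.0:
        raise ParameterError("retention must be in (0, 1]")
    arrays = neg_values if isinstance(neg_values, (list, tuple)) else [neg_values]
    cutoffs = []
    for arr in arrays:
        arr = np.sort(np.asarray(arr, dtype=np.float64).ravel())
        if arr.size == 0:
            raise ParameterError("quantile_gate requires non-empty control values")
        k = int(np.ceil(retention * arr.size))
        cutoffs.append(arr[k - 1])
    return GateThreshold(channel=channel, cutoff=float(max(cutoffs)),
                         retention_used=retention)


def quadrant_gate(
    m: EventMatrix,
    ch_x: str,
    ch_y: str,
    tx: GateThreshold,
    ty: GateThreshold,
    style: str = "axis_aligned",
    line: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> np.ndarray:
    """Label every event with its quadrant: neg / x_pos / y_pos / double_pos.

    ``axis_aligned`` splits at the two cutoffs. ``oblique`` bounds the
    negative region by the line through the two points of ``line``
    (signed-area side test, the side of lower x+y being negative);
    positive-side events are then split into the three positive
    quadrants by the axis cutoffs, with sub-threshold positive-side
    events assigned to the axis they exceed relatively more.
    """
    x, y = m.channel(ch_x), m.channel(ch_y)
    if style == "axis_aligned":
        xp, yp = x > tx.cutoff, y > ty.cutoff
        out = np.where(xp & yp, "double_pos",
                       np.where(xp, "x_pos", np.where(yp, "y_pos", "neg")))
        return out.astype(object)
    if style != "oblique":
        raise ParameterError(f"unknown quadrant style {style!r}")
    if line is None:
        line = ((0.0, ty.cutoff * 2), (tx.cutoff * 2, 0.0))
    (x1, y1), (x2, y2) = line
    if (x1, y1) == (x2, y2):
        raise ParameterError("oblique gate needs two distinct points")
    cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
    # orient so the side containing (min corner) is "negative"
    ref = (x2 - x1) * (min(y.min(initial=0.0), 0.0) - y1) - (y2 - y1) * (
        min(x.min(initial=0.0), 0.0) - x1)
    neg_side = cross * np.sign(ref if ref != 0 else 1.0) > 0
    xp, yp = x > tx.cutoff, y > ty.cutoff
    out = np.full(x.shape, "neg", dtype=object)
    pos = ~neg_side
    out[pos & xp & yp] = "double_pos"
    out[pos & xp & ~yp] = "x_pos"
    out[pos & ~xp & yp] = "y_pos"
    rest = pos & ~xp & ~yp
    rel_x = (x - tx.cutoff) / max(abs(tx.cutoff), 1e-12)
    rel_y = (y - ty.cutoff) / max(abs(ty.cutoff), 1e-12)
    out[rest] = np.where(rel_x[rest] >= rel_y[rest], "x_pos", "y_pos")
    return out


def _control_values(s: StudySet, channel: str,
                    mask_fn=None) -> list[np.ndarray]:
    out = []
    for meta, m in s.select(SampleType.unlabeled_cells):
        v = m.channel(channel)
        if mask_fn is not None:
            v = v[mask_fn(m)]
        if v.size:
            out.append(v)
    if not out:
        raise ParameterError("study has no usable unlabeled-control events")
    return out


def sequential_gating(s: StudySet, c: GatingCriteria) -> GatingResult:
    """Run the three-layer cascade on every labeled-cells sample."""
    for ch in ("CD45", "CD31", "PDPN", "ICAM1", "VCAM1"):
        s.panel.index(ch)  # raises PanelError when missing

    def _gate(channel: str, mask_fn=None) -> GateThreshold:
        t = quantile_gate(_control_values(s, channel, mask_fn), c.retention, channel)
        if c.margin:
            t = GateThreshold(t.channel, t.cutoff * (1.0 + c.margin), t.retention_used)
        return t

    t_cd45 = _gate("CD45")
    neg_mask = lambda m: m.channel("CD45") <= t_cd45.cutoff  # noqa: E731
    t_cd31 = _gate("CD31", neg_mask)
    t_pdpn = _gate("PDPN", neg_mask)
    t_icam = _gate("ICAM1", neg_mask)
    t_vcam = _gate("VCAM1", neg_mask)
    thresholds = {"CD45": t_cd45, "CD31": t_cd31, "PDPN": t_pdpn,
                  "ICAM1": t_icam, "VCAM1": t_vcam}

    frames = []
    for meta, m in s.select(SampleType.labeled_cells):
        layer1 = np.where(m.channel("CD45") > t_cd45.cutoff, "CD45pos", "CD45neg")
        layer2 = np.full(m.n_events, "", dtype=object)
        terminal = np.full(m.n_events, "CD45pos", dtype=object)
        negs = layer1 == "CD45neg"
        if negs.any():
            quad = quadrant_gate(m.take(negs), "CD31", "PDPN", t_cd31, t_pdpn,
                                 style=c.boundary_style)
            pops = np.array([LAYER2_POPULATIONS[q] for q in quad], dtype=object)
            layer2[negs] = pops
            term = pops.copy()
            sub = m.take(negs)
            for parent in ("FRC", "PvC_DN"):
                sel = pops == parent
                if sel.any():
                    q3 = quadrant_gate(sub.take(sel), "ICAM1", "VCAM1",
                                       t_icam, t_vcam, style=c.boundary_style)
                    suffix = {"neg": "ICAM1-VCAM1-", "x_pos": "ICAM1+VCAM1-",
                              "y_pos": "ICAM1-VCAM1+", "double_pos": "ICAM1+VCAM1+"}
                    term[sel] = [f"{parent}/{suffix[q]}" for q in q3]
            terminal[negs] = term
        frames.append(pd.DataFrame({
            "sample_id": meta.sample_id, "day": meta.day, "passage": meta.passage,
            "layer1": layer1, "layer2": layer2, "terminal": terminal,
        }))
    if not frames:
        raise ParameterError("study has no labeled-cells samples to gate")
    labels = pd.concat(frames, ignore_index=True)

    layer_counts = {
        1: labels["layer1"].value_counts(),
        2: labels.loc[labels["layer2"] != "", "layer2"].value_counts(),
        3: labels["terminal"].value_counts(),
    }
    return GatingResult(labels=labels, thresholds=thresholds,
                        counts=layer_counts[3], layer_counts=layer_counts)


@dataclass
class VariationStudyResult:
    """Population counts across gating criteria and their CVs (percent)."""

    counts: pd.DataFrame  # populations x criteria
    cv_percent: pd.Series
    mean_cv_percent: float
    mean_cv_by_layer: dict[int, float] = field(default_factory=dict)


def _cv_percent(counts: pd.DataFrame) -> pd.Series:
    mean = counts.mean(axis=1)
    sd = counts.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    return cv


def gating_variation_study(
    s: StudySet, criteria: list[GatingCriteria]
) -> VariationStudyResult:
    """Rerun the cascade per criterion and quantify count robustness.

    CV per population = sample SD of its counts across criteria divided
    by the mean, as a percent; populations absent under every criterion
    get an undefined (NaN) CV. Per-layer mean CVs expose the compounding
    of gate-placement variation with gating depth.
    """
    if len(criteria) < 2:
        raise ParameterError("variation study needs at least 2 criteria")
    results = [sequential_gating(s, c) for c in criteria]
    names = [f"c{i}_r{c.retention}" + (f"_m{c.margin}" if c.margin else "")
             for i, c in enumerate(criteria)]

    by_layer: dict[int, pd.DataFrame] = {}
    for layer in (1, 2, 3):
        tab = pd.concat([r.layer_counts[layer] for r in results], axis=1).fillna(0)
        tab.columns = names
        by_layer[layer] = tab

    counts = by_layer[3]
    cv = _cv_percent(counts)
    mean_cv_by_layer = {
        layer: float(np.nanmean(_cv_percent(tab))) for layer, tab in by_layer.items()
    }
    return VariationStudyResult(
        counts=counts,
        cv_percent=cv,
        mean_cv_percent=float(np.nanmean(cv)),
        mean_cv_by_layer=mean_cv_by_layer,
    )
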