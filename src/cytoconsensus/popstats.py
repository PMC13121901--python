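"""Probability-binning chi-squared statistics and population reports.

Probability binning defines bins holding (as close as possible to)
equal numbers of *control* events — univariate quantile bins for
per-channel comparisons, a recursive split tree over channels for the
overall multivariate comparison — then scores a test sample by the
two-sample chi-squared of control-vs-test bin occupancy. The reported
``T(x)`` is that chi-squared standardized against a seeded Monte-Carlo
null at the observed sample sizes and bin count, floored at zero, so
that 0 means "indistinguishable from sampling noise" and large values
mean "distinct".

Significance calls are *control-adjusted*: the day-to-day T(x) of the
study's own controls defines the variability level, any control more
variable than the unlabeled-cells control is excluded from that level
(the transform-amplified negative-bead case), and a population is
significant on a channel only when its T(x) against the unlabeled
reference exceeds the level. The bin count never exceeds 10% of the
smaller compared sample.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ParameterError, TooFewEventsError
from .io_model import EventMatrix

DEFAULT_NULL_REPS = 200
DEFAULT_NULL_SEED = 20260914


def _as_2d(x) -> np.ndarray:
    if isinstance(x, EventMatrix):
        return x.values
    x = np.asarray(x, dtype=np.float64)
    return x.reshape(-1, 1) if x.ndim == 1 else x


@dataclass
class _SplitNode:
    channel: int
    threshold: float
    left: "object"
    right: "object"


@dataclass
class _Leaf:
    bin_id: int


@dataclass
class BinningScheme:
    """Equal-control-occupancy binning, univariate or multivariate."""

    dimensionality: str  # "univariate" | "multivariate"
    B: int
    n_control: int
    edges: np.ndarray | None = None  # univariate interior edges, sorted
    tree: object | None = None  # multivariate split tree
    n_channels: int = 1

    def assign(self, values) -> np.ndarray:
        """Bin index in [0, B) for every event."""
        v = _as_2d(values)
        if v.shape[1] != self.n_channels:
            raise ParameterError(
                f"expected {self.n_channels} channels, got {v.shape[1]}")
        if self.dimensionality == "univariate":
            return np.searchsorted(self.edges, v[:, 0], side="right")
        out = np.empty(v.shape[0], dtype=np.int64)

        def walk(node, idx):
            if isinstance(node, _Leaf):
                out[idx] = node.bin_id
                return
            go_left = v[idx, node.channel] <= node.threshold
            walk(node.left, idx[go_left])
            walk(node.right, idx[~go_left])

        walk(self.tree, np.arange(v.shape[0]))
        return out


@dataclass
class TxResult:
    chi2: float
    B: int
    n_control: int
    n_test: int
    tx: float  # max(0, z): 0 means indistinguishable from sampling noise
    z: float = 0.0  # unfloored standardized chi-squared (calibration diagnostic)
    channel: str | None = None


@dataclass
class PopulationTable:
    """Per-population counts and percentages, overall and by passage."""

    table: pd.DataFrame
    passages: tuple[int, ...]

    def to_text(self) -> str:
        return self.table.to_string()


def probability_bins(control, B_requested: int) -> BinningScheme:
    """Build an equal-occupancy binning from a control sample.

    ``B`` is capped at ``floor(n_control / 10)``. Single-channel input
    gives quantile bins; multichannel input gives a recursive split tree
    that, at each split, divides the most populous region between its
    highest-variance channel's sides proportionally to the bin budget
    (the median when the budget splits evenly).
    """
    v = _as_2d(control)
    n = v.shape[0]
    if n == 0:
        raise ParameterError("control sample is empty")
    B = min(int(B_requested), n // 10)
    if B < 2:
        raise TooFewEventsError(
            f"cannot form >= 2 bins from {n} control events "
            f"(requested {B_requested}, cap {n // 10})")
    if v.shape[1] == 1:
        x = np.sort(v[:, 0])
        cuts = [(n * k) // B for k in range(1, B)]
        edges = np.array([(x[c - 1] + x[c]) / 2.0 for c in cuts])
        return BinningScheme("univariate", B=B, n_control=n, edges=edges,
                             n_channels=1)

    next_id = iter(range(B))

    def build(idx: np.ndarray, budget: int):
        if budget == 1:
            return _Leaf(next(next_id))
        sub = v[idx]
        ch = int(np.argmax(sub.var(axis=0)))
        left_budget = (budget + 1) // 2
        m = int(round(idx.size * left_budget / budget))
        m = min(max(m, 1), idx.size - 1)
        order = np.argsort(sub[:, ch], kind="stable")
        thr = (sub[order[m - 1], ch] + sub[order[m], ch]) / 2.0
        go_left = sub[:, ch] <= thr
        # guard against massive ties collapsing one side
        if not go_left.any() or go_left.all():
            go_left = np.zeros(idx.size, dtype=bool)
            go_left[order[:m]] = True
        return _SplitNode(ch, float(thr), build(idx[go_left], left_budget),
                          build(idx[~go_left], budget - left_budget))

    tree = build(np.arange(n), B)
    return BinningScheme("multivariate", B=B, n_control=n, tree=tree,
                         n_channels=v.shape[1])


def _pb_chi2(c_counts: np.ndarray, t_counts: np.ndarray) -> float:
    n_c, n_t = c_counts.sum(), t_counts.sum()
    fc, ft = c_counts / n_c, t_counts / n_t
    denom = fc + ft
    ok = denom > 0
    return float(n_c * n_t / (n_c + n_t)
                 * np.sum((fc[ok] - ft[ok]) ** 2 / denom[ok]))


@functools.lru_cache(maxsize=512)
def _null_moments(n_control: int, n_test: int, B: int,
                  reps: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo mean/SD of the binned chi-squared under the null.

    Replays the full procedure — draw a control sample, build
    equal-occupancy bins from it, bin an independent same-distribution
    test sample, compute the chi-squared — on a continuous reference
    distribution (quantile binning makes the null distribution-free).
    """
    rng = np.random.default_rng(seed)
    cuts = [(n_control * k) // B for k in range(1, B)]
    stats = np.empty(reps)
    for r in range(reps):
        c = np.sort(rng.random(n_control))
        edges = (c[np.array(cuts) - 1] + c[np.array(cuts)]) / 2.0
        t = rng.random(n_test)
        t_counts = np.bincount(np.searchsorted(edges, t, side="right"),
                               minlength=B).astype(np.float64)
        c_counts = np.diff(np.r_[0, cuts, n_control]).astype(np.float64)
        stats[r] = _pb_chi2(c_counts, t_counts)
    return float(stats.mean()), float(stats.std(ddof=1))


def tx_score(
    bins: BinningScheme,
    control,
    test,
    channel: str | None = None,
    null_reps: int = DEFAULT_NULL_REPS,
    null_seed: int = DEFAULT_NULL_SEED,
) -> TxResult:
    """Standardized probability-binning chi-squared of test vs control."""
    c = _as_2d(control)
    t = _as_2d(test)
    if t.shape[0] == 0:
        raise ParameterError("test sample is empty")
    if bins.B > min(c.shape[0], t.shape[0]) // 10:
        raise ParameterError(
            f"B={bins.B} exceeds 10% of the smaller sample "
            f"(n={min(c.shape[0], t.shape[0])}); rebuild with fewer bins")
    c_counts = np.bincount(bins.assign(c), minlength=bins.B).astype(np.float64)
    t_counts = np.bincount(bins.assign(t), minlength=bins.B).astype(np.float64)
    chi2 = _pb_chi2(c_counts, t_counts)
    mu, sd = _null_moments(c.shape[0], t.shape[0], bins.B, null_reps, null_seed)
    z = (chi2 - mu) / sd
    return TxResult(chi2=chi2, B=bins.B, n_control=c.shape[0],
                    n_test=t.shape[0], tx=max(0.0, z), z=z, channel=channel)


def tx_compare(
    control,
    test,
    B_requested: int = 100,
    channel: str | None = None,
    null_reps: int = DEFAULT_NULL_REPS,
    null_seed: int = DEFAULT_NULL_SEED,
) -> TxResult:
    """Convenience: build bins honoring the 10% cap on *both* samples,
    then score."""
    c, t = _as_2d(control), _as_2d(test)
    B = min(int(B_requested), c.shape[0] // 10, t.shape[0] // 10)
    bins = probability_bins(c, B)
    return tx_score(bins, c, t, channel=channel, null_reps=null_reps,
                    null_seed=null_seed)


@dataclass
class AdjustedTxResult:
    """Control-adjusted T(x) for one channel."""

    unlabeled_control_tx: float
    control_tx: dict[str, float]
    excluded_controls: tuple[str, ...]
    control_variability: float
    population_tx: dict[str, float]
    adjusted: dict[str, float]
    significant: dict[str, bool]


def control_adjusted_tx(
    populations: dict[str, np.ndarray],
    unlabeled_by_day: dict[int, np.ndarray],
    controls_by_day: dict[str, dict[int, np.ndarray]],
    channel: str | None = None,
    B_requested: int = 100,
    null_reps: int = DEFAULT_NULL_REPS,
    null_seed: int = DEFAULT_NULL_SEED,
) -> AdjustedTxResult:
    """Adjust population T(x) scores by the controls' day-to-day level.

    The variability level is the maximum day-1-vs-day-2 T(x) over the
    unlabeled-cells control and every other control, *excluding* any
    control whose day-to-day T(x) exceeds the unlabeled one (those
    reflect transform amplification, not biology). Each population is
    scored against the pooled unlabeled reference; significant means
    adjusted T(x) > 0.
    """
    if len(unlabeled_by_day) < 2:
        raise ParameterError("need unlabeled controls on both days")
    days = sorted(unlabeled_by_day)
    kw = dict(B_requested=B_requested, null_reps=null_reps, null_seed=null_seed)
    unl_tx = tx_compare(unlabeled_by_day[days[0]], unlabeled_by_day[days[1]],
                        channel=channel, **kw).tx
    control_tx: dict[str, float] = {}
    excluded: list[str] = []
    for name, by_day in controls_by_day.items():
        if len(by_day) < 2:
            raise ParameterError(f"control {name!r} missing a day")
        d = sorted(by_day)
        control_tx[name] = tx_compare(by_day[d[0]], by_day[d[1]],
                                      channel=channel, **kw).tx
        if control_tx[name] > unl_tx:
            excluded.append(name)
    level = max([unl_tx] + [v for k, v in control_tx.items() if k not in excluded])

    reference = np.concatenate([_as_2d(unlabeled_by_day[d]) for d in days])
    pop_tx, adjusted, significant = {}, {}, {}
    for name, values in populations.items():
        pop_tx[name] = tx_compare(reference, values, channel=channel, **kw).tx
        adjusted[name] = pop_tx[name] - level
        significant[name] = adjusted[name] > 0
    return AdjustedTxResult(
        unlabeled_control_tx=unl_tx, control_tx=control_tx,
        excluded_controls=tuple(excluded), control_variability=level,
        population_tx=pop_tx, adjusted=adjusted, significant=significant)


#: positive-marker pattern -> phenotype name (CD45 omitted patterns work
#: for CD45-dropped panels too)
PHENOTYPES = {
    frozenset({"CD45", "CD31", "PDPN", "ICAM1", "VCAM1"}): "hematopoietic",
    frozenset({"CD31", "PDPN", "ICAM1", "VCAM1"}): "LEC",
    frozenset({"VCAM1"}): "PvC",
    frozenset({"PDPN", "VCAM1"}): "FRC",
    frozenset({"PDPN", "ICAM1", "VCAM1"}): "MRC-like",
}


@dataclass
class PositivityCall:
    positive: dict[str, bool]
    adjusted: dict[str, AdjustedTxResult]
    phenotype: str


def marker_positivity(
    population: EventMatrix,
    unlabeled_by_day: dict[int, EventMatrix],
    controls_by_day: dict[str, dict[int, EventMatrix]],
    B_requested: int = 100,
    null_reps: int = DEFAULT_NULL_REPS,
    null_seed: int = DEFAULT_NULL_SEED,
) -> PositivityCall:
    """Call each channel +/- for one population and name its phenotype.

    A channel is positive when the control-adjusted T(x) against the
    unlabeled reference is significant *and* the population median
    exceeds the pooled unlabeled 99th percentile on that channel (the
    statistical call alone flags any distribution difference, including
    negative shifts).
    """
    if population.n_events == 0:
        raise ParameterError("population is empty")
    panel = population.panel
    positive: dict[str, bool] = {}
    details: dict[str, AdjustedTxResult] = {}
    for ch in panel.channels:
        res = control_adjusted_tx(
            populations={"pop": population.channel(ch)},
            unlabeled_by_day={d: m.channel(ch) for d, m in unlabeled_by_day.items()},
            controls_by_day={name: {d: m.channel(ch) for d, m in by_day.items()}
                             for name, by_day in controls_by_day.items()},
            channel=ch, B_requested=B_requested,
            null_reps=null_reps, null_seed=null_seed)
        details[ch] = res
        ref = np.concatenate([m.channel(ch) for m in unlabeled_by_day.values()])
        guard = np.median(population.channel(ch)) > np.quantile(ref, 0.99)
        positive[ch] = bool(res.significant["pop"] and guard)
    pattern = frozenset(ch for ch, pos in positive.items() if pos)
    phenotype = PHENOTYPES.get(pattern, "unassigned")
    return PositivityCall(positive=positive, adjusted=details, phenotype=phenotype)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def population_table(
    labels: np.ndarray, passages: np.ndarray, order: list[str] | None = None
) -> PopulationTable:
    """Counts and percentages of labeled-cell populations by passage.

    Percentages are of total labeled cells and of each passage's labeled
    cells, rounded half-up to two decimals; a totals row closes the
    table.
    """
    labels = np.asarray(labels)
    passages = np.asarray(passages)
    if labels.shape != passages.shape:
        raise ParameterError("labels and passages must align")
    pas = tuple(sorted(np.unique(passages).tolist()))
    names = order if order is not None else sorted(np.unique(labels).tolist())
    total = labels.size
    rows = []
    for name in names:
        sel = labels == name
        row = {"population": name, "count": int(sel.sum()),
               "pct_total": _round2(100.0 * sel.sum() / total) if total else 0.0}
        for p in pas:
            psel = passages == p
            denom = int(psel.sum())
            row[f"count_P{p}"] = int((sel & psel).sum())
            row[f"pct_P{p}"] = _round2(100.0 * (sel & psel).sum() / denom) \
                if denom else 0.0
        rows.append(row)
    total_row = {"population": "Total labeled cells", "count": total,
                 "pct_total": _round2(100.0) if total else 0.0}
    for p in pas:
        total_row[f"count_P{p}"] = int((passages == p).sum())
        total_row[f"pct_P{p}"] = _round2(100.0)
    rows.append(total_row)
    return PopulationTable(table=pd.DataFrame(rows), passages=pas)
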