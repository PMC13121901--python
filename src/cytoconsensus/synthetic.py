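"""Synthetic two-day cytometry study generator.

Emulates the sample design the analysis assumes: per acquisition day,
five single-stain compensation-bead samples (one sharp negative and one
sharp positive peak each), one unlabeled-cells sample (autofluorescence
only), and one labeled-cells sample drawn from overlapping populations
whose proportions depend on the culture passage profiled that day
(passage 5 on day 1, passage 12 on day 2 in the reference design). A
configurable affine batch effect distorts one channel on one day —
by default a strong ICAM-1 gain loss on day 2, the situation the
bead-anchored normalization exists to correct.

Noise model: each positive signal is log-normal around its linear-scale
median, additively on top of a log-normal autofluorescence floor. This
reproduces the heavy-tailed, orders-of-magnitude span of fluorescence
data; it does not model spillover, acquisition drift, or doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError, ParameterError
from .io_model import (
    ChannelPanel,
    EventMatrix,
    SampleMeta,
    SampleType,
    Scale,
    StudySet,
    reference_panel,
)

#: Labeled-population proportions by passage in the reference design
#: (fractions of labeled cells at passages 5 and 12).
REFERENCE_PROPORTIONS = {
    "hematopoietic": {5: 0.0781, 12: 0.0001},
    "LEC": {5: 0.0544, 12: 0.0027},
    "PvC": {5: 0.0041, 12: 0.0584},
    "FRC": {5: 0.8634, 12: 0.9388},
}


@dataclass(frozen=True)
class PopulationSpec:
    """One generated cell population.

    ``location``/``spread`` map marker channels to the log-normal median
    and log-sigma of that marker's *positive* signal; channels absent
    from ``location`` carry only the autofluorescence floor.
    """

    name: str
    location: dict[str, float]
    spread: dict[str, float]
    proportion_by_passage: dict[int, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.location.values()):
            raise DesignError(f"{self.name}: locations must be positive")
        if any(v <= 0 for v in self.spread.values()):
            raise DesignError(f"{self.name}: spreads must be positive")


@dataclass(frozen=True)
class BatchEffect:
    """Affine acquisition distortion of one channel on one day."""

    channel: str
    gain: float
    offset: float = 0.0
    day: int = 2

    def __post_init__(self):
        if self.gain <= 0:
            raise DesignError("batch-effect gain must be positive")


@dataclass
class StudyDesign:
    panel: ChannelPanel
    populations: list[PopulationSpec]
    bead_positive_location: float = 30_000.0
    bead_positive_spread: float = 0.22
    bead_negative_location: float = 60.0
    bead_negative_spread: float = 0.35
    autofluorescence_location: dict[str, float] = field(default_factory=dict)
    autofluorescence_spread: dict[str, float] = field(default_factory=dict)
    events_per_sample: dict[str, int] = field(
        default_factory=lambda: {"bead": 5000, "unlabeled": 20000, "labeled": 20000})
    batch_effects: list[BatchEffect] = field(default_factory=list)
    passage_by_day: dict[int, int] = field(default_factory=lambda: {1: 5, 2: 12})

    def __post_init__(self):
        chans = set(self.panel.channels)
        for p in self.populations:
            unknown = (set(p.location) | set(p.spread)) - chans
            if unknown:
                raise DesignError(f"population {p.name}: unknown channels {unknown}")
        for be in self.batch_effects:
            if be.channel not in chans:
                raise DesignError(f"batch effect on unknown channel {be.channel}")
        for passage in self.passage_by_day.values():
            total = sum(p.proportion_by_passage.get(passage, 0.0)
                        for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise DesignError(
                    f"population proportions at passage {passage} sum to {total}, not 1")

    def af_location(self, channel: str) -> float:
        return self.autofluorescence_location.get(channel, 250.0)

    def af_spread(self, channel: str) -> float:
        return self.autofluorescence_spread.get(channel, 0.45)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def sample_population(
    p: PopulationSpec,
    passage: int,
    n: int,
    seed: int,
    panel: ChannelPanel | None = None,
    af_location: dict[str, float] | None = None,
    af_spread: dict[str, float] | None = None,
) -> EventMatrix:
    """Draw ``n`` events from one population.

    Each channel with a positive signal is log-normal around the
    population's location; every channel additionally carries a
    log-normal autofluorescence floor. Deterministic per seed.
    """
    if n < 0:
        raise ParameterError("n must be non-negative")
    if panel is None:
        panel = ChannelPanel(tuple(sorted(set(p.location) | set(p.spread))) or
                             ("CH0",))
    for ch in set(p.location) | set(p.spread):
        if ch not in panel.channels:
            raise DesignError(f"population {p.name}: unknown channel {ch}")
    rng = np.random.default_rng(seed)
    cols = []
    for ch in panel.channels:
        floor = _lognormal(rng, (af_location or {}).get(ch, 250.0),
                           (af_spread or {}).get(ch, 0.45), n)
        if ch in p.location:
            cols.append(floor + _lognormal(rng, p.location[ch],
                                           p.spread.get(ch, 0.35), n))
        else:
            cols.append(floor)
    values = np.column_stack(cols) if n else np.empty((0, len(panel)))
    return EventMatrix(values, panel, Scale.linear)


def _apply_batch_effects(values: np.ndarray, panel: ChannelPanel,
                         effects: list[BatchEffect], day: int) -> np.ndarray:
    out = values.copy()
    for be in effects:
        if be.day == day:
            j = panel.index(be.channel)
            out[:, j] = be.gain * out[:, j] + be.offset
    return out


def generate_bead_sample(
    d: StudyDesign, channel: str, day: int, n: int, seed: int,
    positive_fraction: float = 0.5,
) -> tuple[SampleMeta, EventMatrix]:
    """One single-stain compensation-bead sample.

    The stained channel is a mixture of a sharp negative and a sharp
    positive peak (default 50/50); all other channels sit at the
    negative-bead level. The day's batch effects are applied.
    """
    j = d.panel.index(channel)
    rng = np.random.default_rng(seed)
    n_pos = int(rng.binomial(n, positive_fraction))
    values = np.column_stack([
        _lognormal(rng, d.bead_negative_location, d.bead_negative_spread, n)
        for _ in d.panel.channels])
    pos = _lognormal(rng, d.bead_positive_location, d.bead_positive_spread, n_pos)
    values[:n_pos, j] = values[:n_pos, j] + pos
    perm = rng.permutation(n)
    values = values[perm]
    values = _apply_batch_effects(values, d.panel, d.batch_effects, day)
    meta = SampleMeta(sample_id=f"beads_{channel}_day{day}",
                      sample_type=SampleType.bead_single_stain,
                      stain_channel=channel, day=day)
    return meta, EventMatrix(values, d.panel, Scale.linear)


def _unlabeled_sample(d: StudyDesign, day: int, n: int, seed: int
                      ) -> tuple[SampleMeta, EventMatrix]:
    rng = np.random.default_rng(seed)
    values = np.column_stack([
        _lognormal(rng, d.af_location(ch), d.af_spread(ch), n)
        for ch in d.panel.channels])
    values = _apply_batch_effects(values, d.panel, d.batch_effects, day)
    meta = SampleMeta(sample_id=f"unlabeled_day{day}",
                      sample_type=SampleType.unlabeled_cells, day=day)
    return meta, EventMatrix(values, d.panel, Scale.linear)


def _labeled_sample(d: StudyDesign, day: int, n: int, seed: int
                    ) -> tuple[SampleMeta, EventMatrix, np.ndarray]:
    passage = d.passage_by_day[day]
    rng = np.random.default_rng(seed)
    props = np.array([p.proportion_by_passage.get(passage, 0.0)
                      for p in d.populations])
    counts = rng.multinomial(n, props)
    parts, names = [], []
    for p, k in zip(d.populations, counts):
        m = sample_population(
            p, passage, int(k), seed=int(rng.integers(2**31)), panel=d.panel,
            af_location={ch: d.af_location(ch) for ch in d.panel.channels},
            af_spread={ch: d.af_spread(ch) for ch in d.panel.channels})
        parts.append(m.values)
        names.append(np.repeat(p.name, k))
    values = np.concatenate(parts) if parts else np.empty((0, len(d.panel)))
    truth = np.concatenate(names) if names else np.empty(0, dtype=object)
    perm = rng.permutation(n)
    values, truth = values[perm], truth[perm]
    values = _apply_batch_effects(values, d.panel, d.batch_effects, day)
    meta = SampleMeta(sample_id=f"labeled_P{passage}_day{day}",
                      sample_type=SampleType.labeled_cells, day=day,
                      passage=passage)
    return meta, EventMatrix(values, d.panel, Scale.linear), truth


def generate_study(d: StudyDesign, seed: int) -> StudySet:
    """Generate the full two-day study.

    Per day: one single-stain bead sample per panel channel, one
    unlabeled-cells sample, one labeled-cells sample (14 samples total
    for the five-channel reference design). Batch effects apply only to
    their own day. The returned study carries a ``truth`` attribute
    mapping labeled-sample ids to per-event generating-population names.
    """
    rng = np.random.default_rng(seed)
    samples: list[tuple[SampleMeta, EventMatrix]] = []
    truth: dict[str, np.ndarray] = {}
    n_bead = d.events_per_sample.get("bead", 5000)
    n_unl = d.events_per_sample.get("unlabeled", 20000)
    n_lab = d.events_per_sample.get("labeled", 20000)
    for day in sorted(d.passage_by_day):
        for ch in d.panel.channels:
            samples.append(generate_bead_sample(
                d, ch, day, n_bead, seed=int(rng.integers(2**31))))
        samples.append(_unlabeled_sample(d, day, n_unl, seed=int(rng.integers(2**31))))
        meta, m, t = _labeled_sample(d, day, n_lab, seed=int(rng.integers(2**31)))
        samples.append((meta, m))
        truth[meta.sample_id] = t
    study = StudySet(samples)
    study.truth = truth
    return study


def reference_design(
    mrc_fraction: float = 0.0,
    separation: str = "well_separated",
    events_per_sample: dict[str, int] | None = None,
    batch_gain: float = 0.4,
    batch_offset: float = 20.0,
    batch_channel: str = "ICAM1",
) -> StudyDesign:
    """The default study design.

    Four labeled populations follow the profiled passage breakdown
    (passage 5 on day 1, passage 12 on day 2): a hematopoietic
    population positive for all five markers, LEC-like
    (CD31+PDPN+ICAM1+VCAM1+), PvC-like (VCAM1 only), and FRC-like
    (PDPN+VCAM1+). ``mrc_fraction`` carves an MRC-like subpopulation
    (FRC with raised ICAM-1) out of the FRC fraction to exercise
    near-indistinguishable-population behaviour. ``separation`` is
    ``well_separated`` (default) or ``overlapping`` (doubled spreads and
    lowered positive signals, for gating-robustness studies).
    """
    if not 0.0 <= mrc_fraction < 1.0:
        raise ParameterError("mrc_fraction must be in [0, 1)")
    if separation not in ("well_separated", "overlapping"):
        raise ParameterError(f"unknown separation preset {separation!r}")
    hi = separation == "well_separated"
    lvl = 1.0 if hi else 0.25
    sd = 0.35 if hi else 0.7

    def spec(name: str, loc: dict[str, float], props: dict[int, float]) -> PopulationSpec:
        return PopulationSpec(
            name=name,
            location={ch: v * lvl for ch, v in loc.items()},
            spread={ch: sd for ch in loc},
            proportion_by_passage=props,
        )

    frc_props = REFERENCE_PROPORTIONS["FRC"]
    pops = [
        spec("hematopoietic",
             {"CD45": 25_000, "CD31": 8_000, "PDPN": 6_000,
              "ICAM1": 12_000, "VCAM1": 10_000},
             REFERENCE_PROPORTIONS["hematopoietic"]),
        spec("LEC", {"CD31": 15_000, "PDPN": 12_000, "ICAM1": 9_000,
                     "VCAM1": 8_000},
             REFERENCE_PROPORTIONS["LEC"]),
        spec("PvC", {"VCAM1": 18_000}, REFERENCE_PROPORTIONS["PvC"]),
        spec("FRC", {"PDPN": 10_000, "VCAM1": 6_000},
             {k: v * (1 - mrc_fraction) for k, v in frc_props.items()}),
    ]
    if mrc_fraction > 0:
        pops.append(spec("MRC", {"PDPN": 10_000, "ICAM1": 5_000, "VCAM1": 6_000},
                         {k: v * mrc_fraction for k, v in frc_props.items()}))
    return StudyDesign(
        panel=reference_panel(),
        populations=pops,
        events_per_sample=dict(events_per_sample or
                               {"bead": 5000, "unlabeled": 20000, "labeled": 20000}),
        batch_effects=[BatchEffect(channel=batch_channel, gain=batch_gain,
                                   offset=batch_offset, day=2)]
        if batch_gain != 1.0 or batch_offset != 0.0 else [],
    )
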