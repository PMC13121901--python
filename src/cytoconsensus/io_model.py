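"""Event-data containers, scale transforms, and dataset assembly.

The in-memory model is deliberately small: an :class:`EventMatrix` is a
dense ``n_events x n_channels`` float array plus a :class:`ChannelPanel`
and a scale flag, and a :class:`StudySet` is a list of
``(SampleMeta, EventMatrix)`` pairs sharing one panel. Assembly of
pooled datasets (the sample-combination variants used before embedding
and clustering) lives here too.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _fcs
from .errors import AssemblyError, FormatError, PanelError, ParameterError

REFERENCE_CHANNELS = ("CD45", "CD31", "PDPN", "ICAM1", "VCAM1")


class Scale(str, enum.Enum):
    linear = "linear"
    transformed = "transformed"


class SampleType(str, enum.Enum):
    bead_single_stain = "bead_single_stain"
    unlabeled_cells = "unlabeled_cells"
    labeled_cells = "labeled_cells"


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered marker panel; the reference panel is CD45/CD31/PDPN/ICAM1/VCAM1."""

    channels: tuple[str, ...]
    fluorophores: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.channels:
            raise PanelError("panel must contain at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise PanelError(f"duplicate channel names in panel: {self.channels}")
        if self.fluorophores and len(self.fluorophores) != len(self.channels):
            raise PanelError("fluorophores must match channels one-to-one")

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise PanelError(f"channel {channel!r} not in panel {self.channels}") from None

    def __len__(self) -> int:
        return len(self.channels)


def reference_panel() -> ChannelPanel:
    return ChannelPanel(
        channels=REFERENCE_CHANNELS,
        fluorophores=("PE-Cy7", "BV605", "BV421", "PE", "AF647"),
    )


@dataclass
class EventMatrix:
    """Per-event channel intensities.

    ``values`` is ``n_events x n_channels`` float64; ``scale`` records
    whether intensities are raw linear or variance-stabilized.
    """

    values: np.ndarray
    panel: ChannelPanel
    scale: Scale = Scale.linear

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, len(self.panel))
        if self.values.ndim != 2 or self.values.shape[1] != len(self.panel):
            raise PanelError(
                f"values shape {self.values.shape} does not match panel of "
                f"{len(self.panel)} channels"
            )
        if self.values.size and not np.isfinite(self.values).all():
            raise ParameterError("event matrix contains non-finite values")
        self.scale = Scale(self.scale)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.panel.index(name)]

    def take(self, idx: np.ndarray) -> "EventMatrix":
        return EventMatrix(self.values[idx], self.panel, self.scale)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sample_type: SampleType
    stain_channel: str | None = None
    day: int = 1
    passage: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "sample_type", SampleType(self.sample_type))
        if (self.stain_channel is not None) != (
            self.sample_type is SampleType.bead_single_stain
        ):
            raise ParameterError(
                "stain_channel must be set exactly for bead_single_stain samples"
            )
        if (self.passage is not None) != (
            self.sample_type is SampleType.labeled_cells
        ):
            raise ParameterError("passage must be set exactly for labeled_cells samples")


@dataclass
class StudySet:
    """All samples of one study (both acquisition days) on a shared panel."""

    samples: list[tuple[SampleMeta, EventMatrix]] = field(default_factory=list)

    def __post_init__(self):
        panels = {m.panel.channels for _, m in self.samples}
        if len(panels) > 1:
            raise PanelError("all samples in a study must share one panel")

    @property
    def panel(self) -> ChannelPanel:
        if not self.samples:
            raise PanelError("empty study has no panel")
        return self.samples[0][1].panel

    @property
    def days(self) -> list[int]:
        return sorted({meta.day for meta, _ in self.samples})

    def select(self, sample_type: SampleType | None = None,
               day: int | None = None,
               stain_channel: str | None = None) -> list[tuple[SampleMeta, EventMatrix]]:
        out = []
        for meta, m in self.samples:
            if sample_type is not None and meta.sample_type is not SampleType(sample_type):
                continue
            if day is not None and meta.day != day:
                continue
            if stain_channel is not None and meta.stain_channel != stain_channel:
                continue
            out.append((meta, m))
        return out

    def map_values(self, fn) -> "StudySet":
        """Apply ``fn(meta, EventMatrix) -> EventMatrix`` to every sample."""
        return StudySet([(meta, fn(meta, m)) for meta, m in self.samples])


@dataclass(frozen=True)
class TransformSpec:
    """Variance-stabilizing transform: arcsinh(value / cofactor).

    The 150 default is the conventional cofactor for conventional
    (non-mass) fluorescence cytometry.
    """

    kind: str = "arcsinh"
    cofactor: float | dict[str, float] = 150.0

    def __post_init__(self):
        if self.kind != "arcsinh":
            raise ParameterError(f"unknown transform kind {self.kind!r}")
        cof = self.cofactor
        values = cof.values() if isinstance(cof, dict) else [cof]
        if any(c <= 0 for c in values):
            raise ParameterError("cofactor must be positive")

    def cofactor_for(self, channel: str) -> float:
        if isinstance(self.cofactor, dict):
            return float(self.cofactor.get(channel, 150.0))
        return float(self.cofactor)


@dataclass(frozen=True)
class DatasetVariant:
    """One sample-combination variant for pooled analysis.

    ``include_beads``: none | all | limited. ``cells``: all | limited |
    gated_cd45neg | gated_cd45neg_limited. ``drop_cd45_channel`` removes
    the CD45 column and is only meaningful for CD45-negative variants.
    """

    include_beads: str = "all"
    cells: str = "all"
    drop_cd45_channel: bool = False

    def __post_init__(self):
        if self.include_beads not in ("none", "all", "limited"):
            raise ParameterError(f"bad include_beads {self.include_beads!r}")
        if self.cells not in ("all", "limited", "gated_cd45neg", "gated_cd45neg_limited"):
            raise ParameterError(f"bad cells {self.cells!r}")
        if self.drop_cd45_channel and not self.cells.startswith("gated_cd45neg"):
            raise ParameterError("drop_cd45_channel requires a gated_cd45neg cells variant")


def read_events(path: str, format: str = "csv") -> EventMatrix:
    """Read an event table from CSV (header row) or FCS 3.0/3.1 list mode.

    FCS values are returned on the linear scale with log-amplification
    and gain keywords applied; channel names come from ``$PnN`` with a
    ``$PnS`` fallback.
    """
    if format == "csv":
        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
        with open(path) as fh:  # pandas mangles duplicate headers; check raw
            for line in fh:
                if not line.startswith("#") and line.strip():
                    names = [c.strip() for c in line.rstrip("\n").split(",")]
                    break
            else:
                raise FormatError(f"{path}: no header row")
        values = df.to_numpy(dtype=np.float64)
    elif format == "fcs":
        values, names, _ = _fcs.read_fcs(path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    if len(set(names)) != len(names):
        raise PanelError(f"{path}: duplicate channel names {names}")
    return EventMatrix(values, ChannelPanel(tuple(names)), Scale.linear)


def write_events_csv(path: str, m: EventMatrix, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(m.values, columns=list(m.panel.channels)).to_csv(fh, index=False)


def write_events_fcs(path: str, m: EventMatrix) -> None:
    """Fixture writer: float32 FCS 3.1, linear scale."""
    if m.scale is not Scale.linear:
        raise ParameterError("FCS fixtures are written on the linear scale")
    _fcs.write_fcs(path, m.values, list(m.panel.channels))


def apply_transform(m: EventMatrix, t: TransformSpec) -> EventMatrix:
    """arcsinh(value / cofactor) per channel; monotone, odd, defined for
    the negative values compensation produces."""
    if m.scale is not Scale.linear:
        raise ParameterError("apply_transform expects linear-scale input")
    cof = np.array([t.cofactor_for(c) for c in m.panel.channels])
    return EventMatrix(np.arcsinh(m.values / cof), m.panel, Scale.transformed)


def inverse_transform(m: EventMatrix, t: TransformSpec) -> EventMatrix:
    if m.scale is not Scale.transformed:
        raise ParameterError("inverse_transform expects transformed input")
    cof = np.array([t.cofactor_for(c) for c in m.panel.channels])
    return EventMatrix(np.sinh(m.values) * cof, m.panel, Scale.linear)


def _included(meta: SampleMeta, v: DatasetVariant) -> bool:
    if meta.sample_type is SampleType.bead_single_stain:
        return v.include_beads != "none"
    return True


def assemble_dataset(
    s: StudySet,
    v: DatasetVariant,
    cd45_threshold: float | None = None,
    seed: int = 0,
) -> tuple[EventMatrix, pd.DataFrame]:
    """Concatenate study samples into one pooled matrix per a variant.

    Returns the pooled :class:`EventMatrix` and a per-event provenance
    frame (sample_id, sample_type, stain_channel, day, passage,
    source_row). "limited" variants downsample every included sample,
    without replacement, to the smallest included sample's size, using
    ``seed``. Gated variants keep only events with CD45 below
    ``cd45_threshold``; ``drop_cd45_channel`` then removes that column.
    """
    gated = v.cells.startswith("gated_cd45neg")
    if gated and cd45_threshold is None:
        raise ParameterError("gated_cd45neg variants require cd45_threshold")
    rng = np.random.default_rng(seed)

    kept: list[tuple[SampleMeta, np.ndarray, np.ndarray]] = []  # meta, values, rows
    for meta, m in s.samples:
        if not _included(meta, v):
            continue
        rows = np.arange(m.n_events)
        vals = m.values
        if gated:
            ch = m.channel("CD45")
            mask = ch < cd45_threshold
            vals, rows = vals[mask], rows[mask]
        kept.append((meta, vals, rows))
    if not kept:
        raise AssemblyError("variant selects no samples")

    limit_beads = v.include_beads == "limited"
    limit_cells = v.cells in ("limited", "gated_cd45neg_limited")
    if limit_beads or limit_cells:
        smallest = min(vals.shape[0] for _, vals, _ in kept)
        out = []
        for meta, vals, rows in kept:
            is_bead = meta.sample_type is SampleType.bead_single_stain
            limit = limit_beads if is_bead else limit_cells
            if limit and vals.shape[0] > smallest:
                idx = np.sort(rng.choice(vals.shape[0], size=smallest, replace=False))
                vals, rows = vals[idx], rows[idx]
            out.append((meta, vals, rows))
        kept = out

    values = np.concatenate([vals for _, vals, _ in kept], axis=0)
    if values.shape[0] == 0:
        raise AssemblyError("assembled dataset is empty")
    panel = s.panel
    if v.drop_cd45_channel:
        j = panel.index("CD45")
        values = np.delete(values, j, axis=1)
        chans = tuple(c for c in panel.channels if c != "CD45")
        fluor = tuple(f for i, f in enumerate(panel.fluorophores) if i != j) \
            if panel.fluorophores else ()
        panel = ChannelPanel(chans, fluor)

    labels = pd.DataFrame({
        "sample_id": np.concatenate(
            [np.repeat(meta.sample_id, vals.shape[0]) for meta, vals, _ in kept]),
        "sample_type": np.concatenate(
            [np.repeat(meta.sample_type.value, vals.shape[0]) for meta, vals, _ in kept]),
        "stain_channel": np.concatenate(
            [np.repeat(meta.stain_channel or "", vals.shape[0]) for meta, vals, _ in kept]),
        "day": np.concatenate(
            [np.repeat(meta.day, vals.shape[0]) for meta, vals, _ in kept]),
        "passage": np.concatenate(
            [np.repeat(-1 if meta.passage is None else meta.passage, vals.shape[0])
             for meta, vals, _ in kept]),
        "source_row": np.concatenate([rows for _, _, rows in kept]),
    })
    labels.attrs["seed"] = seed
    scale = s.samples[0][1].scale
    return EventMatrix(values, panel, scale), labels
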