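"""Cross-algorithm consensus population identification.

The manual procedure this module formalizes: run several clusterers of
different inductive bias, look for the patterns they agree on, anchor
the easily identified control populations (positive compensation beads,
negative beads, unlabeled cells), and merge or keep apart the remaining
labeled-cell clusters using a distribution-difference statistic and a
robust location-similarity check. The formal version is order-free and
reproducible:

1. a co-association matrix over a seeded event subsample records the
   fraction of clusterings placing each event pair together;
2. average-linkage grouping of (1 - co-association), cut at a
   configurable agreement level, yields consensus clusters, extended to
   all events by nearest group centroid in marker space;
3. clusters dominated by one control sample type are anchored to that
   control role and same-role clusters merged;
4. remaining labeled-cell clusters merge pairwise when their robust
   standardized location difference is below a threshold (heavy
   overlap: algorithmic splits of one population are spatially
   coherent, so a distribution test alone would keep them apart) *or*
   their control-adjusted T(x) is non-significant on every channel
   (statistically indistinguishable), repeated to a fixed point
   (smallest cluster-id pair first); pairs that merge on the T(x) rule
   despite exceeding the similarity threshold are flagged "borderline"
   in the audit log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError
from .highdim import ClusteringResult, EmbeddingSet, detect_islands
from .io_model import EventMatrix
from .popstats import DEFAULT_NULL_REPS, DEFAULT_NULL_SEED, tx_compare

ROLE_LABELED = "labeled_population"


@dataclass
class CoassociationSummary:
    subset: np.ndarray  # event indices of the subsample
    matrix: np.ndarray  # (s, s) pairwise co-clustering fractions

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != self.subset.size:
            raise ParameterError("co-association matrix/subset size mismatch")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
            raise ParameterError("co-association matrix must be symmetric with unit diagonal")


@dataclass(frozen=True)
class ClusterSimilarity:
    per_channel: dict[str, float]
    aggregate: float  # max over channels


@dataclass
class ConsensusPopulations:
    """Final event-to-population assignment with control anchors."""

    labels: np.ndarray  # per-event population name
    roles: dict[str, str]  # population name -> role
    audit: list[dict] = field(default_factory=list)
    meta: pd.DataFrame | None = None  # per-event provenance (sample/day/passage)

    @property
    def population_names(self) -> list[str]:
        return sorted(self.roles)

    def counts_by_sample(self) -> pd.DataFrame:
        if self.meta is None:
            raise ParameterError("no per-event metadata attached")
        df = pd.DataFrame({"population": self.labels,
                           "sample_id": self.meta["sample_id"].to_numpy(),
                           "passage": self.meta["passage"].to_numpy()})
        return df.groupby(["population", "sample_id"]).size().unstack(fill_value=0)


def build_coassociation(
    clusterings: list[ClusteringResult],
    subsample: int = 5000,
    seed: int = 0,
) -> CoassociationSummary:
    """Pairwise fraction of clusterings that co-cluster each event pair,
    over a uniform seeded subsample (cap ``subsample`` events)."""
    if len(clusterings) < 2:
        raise ParameterError("need at least 2 clusterings")
    sizes = {c.labels.size for c in clusterings}
    if len(sizes) != 1:
        raise ParameterError("clusterings cover different event sets")
    n = sizes.pop()
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(n, size=min(subsample, n), replace=False))
    acc = np.zeros((subset.size, subset.size))
    for c in clusterings:
        lab = c.labels[subset]
        acc += (lab[:, None] == lab[None, :])
    return CoassociationSummary(subset=subset, matrix=acc / len(clusterings))


def consensus_partition(
    c: CoassociationSummary,
    cut: float,
    m: EventMatrix | None = None,
) -> np.ndarray:
    """Average-linkage grouping of (1 - co-association) cut at (1 - cut).

    Returns per-event labels for all events of ``m`` (events outside the
    subsample are assigned to the nearest group centroid in marker
    space) or, when ``m`` is omitted, labels for the subsample only.
    """
    if not 0.0 <= cut <= 1.0:
        raise ParameterError("cut must be in [0, 1]")
    d = 1.0 - c.matrix
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    sub_labels = fcluster(z, t=1.0 - cut, criterion="distance") - 1
    if m is None:
        return sub_labels
    centroids = np.stack([
        m.values[c.subset[sub_labels == g]].mean(axis=0)
        for g in np.unique(sub_labels)])
    # nearest-centroid extension, chunked to bound memory
    out = np.empty(m.n_events, dtype=np.int64)
    step = max(1, int(5e7 // max(centroids.size, 1)))
    for s in range(0, m.n_events, step):
        blk = m.values[s:s + step]
        d2 = ((blk[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        out[s:s + step] = d2.argmin(1)
    out[c.subset] = sub_labels
    return out


def cluster_similarity(
    m: EventMatrix,
    labels: np.ndarray,
    a: int,
    b: int,
    mad_floor: float = 1e-6,
) -> ClusterSimilarity:
    """Robust standardized location difference between two clusters.

    Per channel: |median(a) - median(b)| / pooled scaled MAD (1.4826 *
    median absolute deviation, root-mean-square pooled across the two
    clusters, floored at ``mad_floor``). Aggregate is the max over
    channels; symmetric in a and b.
    """
    va, vb = m.values[labels == a], m.values[labels == b]
    if va.shape[0] == 0 or vb.shape[0] == 0:
        raise ParameterError("both clusters must be non-empty")
    per: dict[str, float] = {}
    for j, ch in enumerate(m.panel.channels):
        med_a, med_b = np.median(va[:, j]), np.median(vb[:, j])
        s_a = 1.4826 * np.median(np.abs(va[:, j] - med_a))
        s_b = 1.4826 * np.median(np.abs(vb[:, j] - med_b))
        pooled = max(np.sqrt((s_a**2 + s_b**2) / 2.0), mad_floor)
        per[ch] = float(abs(med_a - med_b) / pooled)
    return ClusterSimilarity(per_channel=per, aggregate=max(per.values()))


def _control_levels(
    m: EventMatrix,
    meta: pd.DataFrame,
    B_requested: int,
    null_reps: int,
    null_seed: int,
) -> dict[str, float]:
    """Per-channel control day-to-day T(x) level with the exclusion rule."""
    days = sorted(meta.loc[meta["sample_type"] == "unlabeled_cells", "day"].unique())
    if len(days) < 2:
        return {}
    levels: dict[str, float] = {}
    unl = {d: m.values[(meta["sample_type"] == "unlabeled_cells").to_numpy()
                       & (meta["day"] == d).to_numpy()] for d in days[:2]}
    stains = sorted(x for x in meta["stain_channel"].unique() if x)
    for j, ch in enumerate(m.panel.channels):
        unl_tx = tx_compare(unl[days[0]][:, j], unl[days[1]][:, j],
                            B_requested=B_requested, null_reps=null_reps,
                            null_seed=null_seed).tx
        level = unl_tx
        for stain in stains:
            sel = (meta["sample_type"] == "bead_single_stain").to_numpy() \
                & (meta["stain_channel"] == stain).to_numpy()
            byday = [m.values[sel & (meta["day"] == d).to_numpy(), j]
                     for d in days[:2]]
            if min(b.size for b in byday) < 20:
                continue
            ctl_tx = tx_compare(byday[0], byday[1], B_requested=B_requested,
                                null_reps=null_reps, null_seed=null_seed).tx
            if ctl_tx <= unl_tx:  # exclusion rule: over-variable controls dropped
                level = max(level, ctl_tx)
        levels[ch] = level
    return levels


def anchor_and_merge(
    m: EventMatrix,
    labels: np.ndarray,
    meta: pd.DataFrame,
    anchor_fraction: float = 0.9,
    similarity_threshold: float = 3.0,
    B_requested: int = 100,
    merge_subsample: int = 4000,
    null_reps: int = DEFAULT_NULL_REPS,
    null_seed: int = DEFAULT_NULL_SEED,
    seed: int = 0,
) -> ConsensusPopulations:
    """Anchor control clusters and merge labeled clusters to a fixed point.

    See the module docstring for the procedure. ``meta`` is the
    per-event provenance frame produced by dataset assembly.
    """
    labels = np.asarray(labels).copy()
    if labels.size != m.n_events or len(meta) != m.n_events:
        raise ParameterError("labels/meta must align with the event matrix")
    audit: list[dict] = []
    rng = np.random.default_rng(seed)

    stype = meta["sample_type"].to_numpy()
    stain = meta["stain_channel"].to_numpy()
    has_controls = bool(np.isin(stype, ("bead_single_stain", "unlabeled_cells")).any())
    if not has_controls:
        warnings.warn("no control samples present; anchoring skipped", stacklevel=2)

    # --- step 1: control anchoring ---------------------------------------
    roles: dict[int, str] = {}
    for cid in np.unique(labels):
        sel = labels == cid
        n = int(sel.sum())
        frac_bead = (stype[sel] == "bead_single_stain").mean()
        frac_unl = (stype[sel] == "unlabeled_cells").mean()
        role = ROLE_LABELED
        if has_controls and frac_bead >= anchor_fraction:
            stains, counts = np.unique(stain[sel][stain[sel] != ""], return_counts=True)
            top = counts.max() / n if counts.size else 0.0
            if top >= anchor_fraction:
                role = f"bead_control:{stains[counts.argmax()]}"
            else:
                role = "negative_beads"
        elif has_controls and frac_unl >= anchor_fraction:
            role = "unlabeled_cells"
        roles[int(cid)] = role
        audit.append({"action": "anchor", "cluster": int(cid), "n": n,
                      "role": role, "bead_fraction": round(float(frac_bead), 4),
                      "unlabeled_fraction": round(float(frac_unl), 4)})

    # merge same-role control clusters
    by_role: dict[str, list[int]] = {}
    for cid, role in roles.items():
        if role != ROLE_LABELED:
            by_role.setdefault(role, []).append(cid)
    for role, cids in by_role.items():
        keep = min(cids)
        for cid in cids:
            if cid != keep:
                labels[labels == cid] = keep
                audit.append({"action": "merge_role", "from": cid, "into": keep,
                              "role": role})
        roles = {c: r for c, r in roles.items() if c not in set(cids) - {keep}}

    # --- step 2: T(x)-guided merging of labeled clusters ------------------
    levels = _control_levels(m, meta, B_requested, null_reps, null_seed) \
        if has_controls else {}

    def sub(values: np.ndarray) -> np.ndarray:
        if values.shape[0] <= merge_subsample:
            return values
        idx = rng.choice(values.shape[0], size=merge_subsample, replace=False)
        return values[idx]

    def mergeable(a: int, b: int) -> tuple[bool, bool, dict]:
        sim = cluster_similarity(m, labels, a, b)
        if sim.aggregate < similarity_threshold:  # heavy overlap: merge
            return True, False, {"similarity": round(sim.aggregate, 3)}
        va, vb = sub(m.values[labels == a]), sub(m.values[labels == b])
        if min(va.shape[0], vb.shape[0]) < 20:
            return False, False, {"tiny": True,
                                  "similarity": round(sim.aggregate, 3)}
        tx_ok = True
        per_tx = {}
        for j, ch in enumerate(m.panel.channels):
            r = tx_compare(va[:, j], vb[:, j], B_requested=B_requested,
                           null_reps=null_reps, null_seed=null_seed)
            adj = r.tx - levels.get(ch, 0.0)
            per_tx[ch] = round(adj, 3)
            if adj > 0:
                tx_ok = False
                break
        return tx_ok, tx_ok, \
            {"adjusted_tx": per_tx, "similarity": round(sim.aggregate, 3)}

    changed = True
    rejected: set[tuple[int, int]] = set()
    while changed:
        changed = False
        lab_ids = sorted(c for c, r in roles.items() if r == ROLE_LABELED)
        for i, a in enumerate(lab_ids):
            for b in lab_ids[i + 1:]:
                if (a, b) in rejected:
                    continue
                ok, borderline, info = mergeable(a, b)
                if ok:
                    labels[labels == b] = a
                    roles.pop(b)
                    audit.append({"action": "merge_tx", "from": b, "into": a, **info})
                    changed = True
                    break
                rejected.add((a, b))
                audit.append({"action": "keep" if not borderline else "borderline",
                              "pair": (a, b), **info})
            if changed:
                rejected = set()  # cluster contents changed; re-test pairs
                break

    # --- final naming ------------------------------------------------------
    name_of: dict[int, str] = {}
    lab_ids = sorted(c for c, r in roles.items() if r == ROLE_LABELED)
    # order labeled populations by descending size for stable human-facing names
    lab_ids.sort(key=lambda c: -(labels == c).sum())
    for k, cid in enumerate(lab_ids, start=1):
        name_of[cid] = f"population_{k}"
    for cid, role in roles.items():
        if role != ROLE_LABELED:
            name_of[cid] = role.replace("bead_control:", "bead_")
    final = np.array([name_of[c] for c in labels], dtype=object)
    final_roles = {name_of[c]: roles[c] for c in roles}
    return ConsensusPopulations(labels=final, roles=final_roles, audit=audit,
                                meta=meta)


def cross_embedding_consistency(
    p: ConsensusPopulations,
    e: EmbeddingSet,
    bandwidth: float = 1.0,
    density_quantile: float = 0.25,
    min_jaccard: float = 0.5,
) -> dict[str, float]:
    """Fraction of embeddings where each population matches a density island.

    For every population and layout, the best Jaccard overlap between
    the population's events and any island is computed; the score is the
    fraction of layouts where that best overlap reaches ``min_jaccard``.
    """
    n = p.labels.size
    scores: dict[str, list[float]] = {name: [] for name in p.roles}
    for layout in e.layouts.values():
        if layout.shape[0] != n:
            raise ParameterError("embedding does not cover the population events")
        islands = detect_islands(layout, bandwidth=bandwidth,
                                 density_quantile=density_quantile)
        island_ids = np.unique(islands[islands >= 0])
        for name in p.roles:
            sel = p.labels == name
            best = 0.0
            for isl in island_ids:
                isel = islands == isl
                inter = float((sel & isel).sum())
                union = float((sel | isel).sum())
                if union:
                    best = max(best, inter / union)
            scores[name].append(best)
    return {name: float(np.mean([b >= min_jaccard for b in bests])) if bests else 0.0
            for name, bests in scores.items()}
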