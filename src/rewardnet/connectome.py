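"""FA-weighted reward-network construction.

Each edge of the 24-node network carries, per subject, a non-negative
streamline (connective-value) voxel map and shares the subject's FA map on a
common grid.  The streamline region of an edge is the set of voxels whose
across-subject streamline values are significantly above zero (one-sample t,
one-sided, uncorrected alpha); the edge's strength for a subject is the mean
FA over that region.  Strengths assemble into a symmetric 24x24 matrix per
subject, summarized over the control / driving / between-subnetwork (BTN)
edge classes and over any designated set of group-difference (Diff) edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas import NodeAtlas, edge_label


class EmptyRegionError(ValueError):
    """Raised when an edge strength is requested over an empty region."""


@dataclass
class EdgeVoxelData:
    """Per-edge stack of subject streamline maps plus subject FA maps.

    ``streamline`` and ``fa`` are arrays of shape ``(n_subjects, *grid)``;
    ``fa`` is typically a shared view across edges.
    """

    edge: tuple[str, str]
    subjects: list[str]
    streamline: np.ndarray
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.streamline = np.asarray(self.streamline)
        self.fa = np.asarray(self.fa)
        n = len(self.subjects)
        if self.streamline.shape[0] != n or self.fa.shape[0] != n:
            raise ValueError(
                f"edge {edge_label(self.edge)}: maps for {self.streamline.shape[0]} "
                f"subjects but {n} subject ids"
            )
        if self.streamline.shape != self.fa.shape:
            raise ValueError("streamline and FA maps must share the grid shape")
        if np.any(self.streamline < 0):
            raise ValueError("streamline values must be non-negative")
        if np.any((self.fa < 0) | (self.fa > 1)):
            raise ValueError("FA values must lie in [0, 1]")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.streamline.shape[1:]


@dataclass
class StreamlineRegion:
    """Boolean voxel mask supporting one edge, estimated from one group."""

    edge: tuple[str, str]
    group: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return not self.mask.any()


@dataclass
class ConnectivityRecord:
    """One subject's symmetric 24x24 FA-strength matrix."""

    subject: str
    matrix: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (24, 24):
            raise ValueError(f"matrix must be 24x24, got {self.matrix.shape}")
        off = ~np.eye(24, dtype=bool)
        m, mt = self.matrix[off], self.matrix.T[off]
        both = ~(np.isnan(m) & np.isnan(mt))
        if not np.allclose(m[both], mt[both], equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def strength(self, edge: tuple[str, str]) -> float:
        i = self.node_labels.index(edge[0])
        j = self.node_labels.index(edge[1])
        return float(self.matrix[i, j])


def define_streamline_region(
    edge_data: EdgeVoxelData,
    alpha: float = 0.05,
    group: str = "",
    subject_sel: np.ndarray | None = None,
) -> StreamlineRegion:
    """Voxels whose streamline values are significantly above zero.

    A one-sample t-test against zero is applied voxelwise across subjects,
    one-sided (greater), at ``alpha`` uncorrected.  Zero-variance voxels are
    decided by the limiting t: a constant positive value is included, a
    constant zero excluded.

    ``subject_sel`` optionally restricts the test to a boolean subset of the
    subjects (the estimating group).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    maps = edge_data.streamline
    if subject_sel is not None:
        subject_sel = np.asarray(subject_sel, dtype=bool)
        if subject_sel.shape != (maps.shape[0],):
            raise ValueError("subject selector length must match subject count")
        maps = maps[subject_sel]
    n = maps.shape[0]
    if n < 2:
        raise ValueError(
            f"edge {edge_label(edge_data.edge)}: streamline-region estimation "
            f"needs >= 2 subjects, got {n}"
        )
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    mask = np.zeros(maps.shape[1:], dtype=bool)
    # constant positive => t -> +inf => included; constant zero => excluded
    mask[zero_var] = mean[zero_var] > 0
    if np.any(~zero_var):
        t = np.zeros_like(mean)
        t[~zero_var] = mean[~zero_var] / (sd[~zero_var] / np.sqrt(n))
        p = stats.t.sf(t, df=n - 1)
        mask[~zero_var] = p[~zero_var] < alpha
    return StreamlineRegion(edge=edge_data.edge, group=group, mask=mask)


def edge_strength(fa_map: np.ndarray, region: StreamlineRegion) -> float:
    """Mean FA over the region's voxels."""
    if region.empty:
        raise EmptyRegionError(
            f"edge {edge_label(region.edge)}: empty streamline region, "
            "strength undefined"
        )
    fa_map = np.asarray(fa_map)
    if fa_map.shape != region.mask.shape:
        raise ValueError("FA map and region mask grids differ")
    return float(fa_map[region.mask].mean())


def estimate_regions(
    voxel_data: dict[tuple[str, str], EdgeVoxelData],
    groups: dict[str, str],
    alpha: float = 0.05,
    region_mode: str = "group",
) -> dict[tuple[tuple[str, str], str], StreamlineRegion]:
    """Streamline regions per (edge, group), or per edge pooled ('union').

    In ``group`` mode one region is estimated per group from that group's
    subjects.  In ``union`` mode the per-group masks are OR-ed into a single
    region shared by all subjects (keyed by group ``'union'``).
    """
    if region_mode not in ("group", "union"):
        raise ValueError(f"unknown region mode {region_mode!r}")
    group_levels = sorted(set(groups.values()))
    regions: dict[tuple[tuple[str, str], str], StreamlineRegion] = {}
    for edge, data in voxel_data.items():
        sel = {
            g: np.array([groups[s] == g for s in data.subjects]) for g in group_levels
        }
        per_group = {
            g: define_streamline_region(data, alpha=alpha, group=g, subject_sel=sel[g])
            for g in group_levels
        }
        if region_mode == "group":
            for g, reg in per_group.items():
                regions[(edge, g)] = reg
        else:
            mask = np.zeros(data.grid_shape, dtype=bool)
            for reg in per_group.values():
                mask |= reg.mask
            regions[(edge, "union")] = StreamlineRegion(
                edge=edge, group="union", mask=mask
            )
    return regions


def build_connectivity(
    voxel_data: dict[tuple[str, str], EdgeVoxelData],
    atlas: NodeAtlas,
    groups: dict[str, str],
    alpha: float = 0.05,
    region_mode: str = "group",
    regions: dict[tuple[tuple[str, str], str], StreamlineRegion] | None = None,
) -> list[ConnectivityRecord]:
    """Assemble one symmetric strength matrix per subject.

    Each subject's strength on an edge is the mean FA over that edge's
    streamline region — their own group's region in ``group`` mode, the
    pooled region in ``union`` mode.  Edges with empty regions are set to
    NaN with a warning rather than silently zeroed.
    """
    expected = set(atlas.edges())
    missing_edges = expected - set(voxel_data)
    if missing_edges:
        some = ", ".join(edge_label(e) for e in sorted(missing_edges)[:3])
        raise ValueError(f"missing voxel data for {len(missing_edges)} edges ({some} ...)")
    if regions is None:
        regions = estimate_regions(voxel_data, groups, alpha=alpha, region_mode=region_mode)

    subjects = sorted(groups)
    n_empty = 0
    mats = {s: np.zeros((24, 24)) for s in subjects}
    labels = atlas.labels
    for edge in atlas.edges():
        data = voxel_data[edge]
        row = {s: k for k, s in enumerate(data.subjects)}
        i, j = atlas.index(edge[0]), atlas.index(edge[1])
        for s in subjects:
            if s not in row:
                raise ValueError(
                    f"subject {s!r} has no map for edge {edge_label(edge)}"
                )
            key = (edge, groups[s] if region_mode == "group" else "union")
            reg = regions[key]
            if reg.empty:
                val = np.nan
                n_empty += 1
            else:
                val = edge_strength(data.fa[row[s]], reg)
            mats[s][i, j] = mats[s][j, i] = val
    if n_empty:
        warnings.warn(
            f"{n_empty} subject-edge strengths undefined (empty regions); set to NaN",
            stacklevel=2,
        )
    return [
        ConnectivityRecord(subject=s, matrix=mats[s], node_labels=labels)
        for s in subjects
    ]


def subnetwork_means(
    record: ConnectivityRecord,
    atlas: NodeAtlas,
    diff_edges: list[tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Mean edge strength over Control, Driving, BTN and Diff edge sets.

    The Diff mean is NaN when ``diff_edges`` is empty or None (flagged, not
    silently zero).
    """
    all_edges = set(atlas.edges())
    diff_edges = list(diff_edges or [])
    for e in diff_edges:
        if e not in all_edges:
            raise ValueError(f"unknown edge {edge_label(e)} in diff set")
    out: dict[str, float] = {}
    for cls, name in (("control", "control"), ("driving", "driving"), ("btn", "btn")):
        edges = atlas.edges_of_class(cls)
        out[name] = float(np.mean([record.strength(e) for e in edges]))
    if diff_edges:
        out["diff"] = float(np.mean([record.strength(e) for e in diff_edges]))
    else:
        out["diff"] = float("nan")
    return out
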