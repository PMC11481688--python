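"""Temporal grouping of blinks into molecules; spatial clustering into particles.

Temporal grouping links repeated blinking of one fluorophore: within a single
channel, two localizations are linked when they are at most ``max_distance``
apart and their frames differ by at most ``frame_gap + 1``; molecules are the
connected components of that graph, positioned at the mean of their
localizations.  Channels are never merged (sequential acquisition).

Spatial clustering then takes the cross-channel molecule set and returns the
connected components of the pairwise <=``link_radius`` graph, keeping only
components with strictly more than ``min_molecules`` members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from evpipe.localization_io import Channel, LocalizationTable

MOLECULE_COLUMNS = [
    "molecule_id",
    "channel",
    "x",
    "y",
    "n_locs",
    "first_frame",
    "last_frame",
]

DEFAULT_LINK_RADIUS_NM = 150.0
DEFAULT_MIN_MOLECULES = 15


@dataclass
class GroupingParams:
    """Temporal-grouping parameters (defaults: frame gap 2, 30 nm)."""

    frame_gap: int = 2
    max_distance: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_gap < 0:
            raise ValueError("frame_gap must be >= 0")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


def _component_labels(xy: np.ndarray, pairs: np.ndarray, n: int) -> np.ndarray:
    if len(pairs) == 0:
        return np.arange(n)
    i, j = pairs[:, 0], pairs[:, 1]
    graph = sparse.coo_matrix(
        (np.ones(len(i), dtype=np.int8), (i, j)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def group_temporally(
    table: LocalizationTable,
    params: GroupingParams | None = None,
    return_labels: bool = False,
):
    """Group localizations into molecules, one channel at a time.

    Returns a molecule table (``MOLECULE_COLUMNS``).  With
    ``return_labels=True`` also returns an int array aligned with
    ``table.df`` rows giving each localization's molecule_id.

    The grouping is exactly the connected components of the spatio-temporal
    linking graph (edges: same channel, distance <= max_distance, frame
    difference <= frame_gap + 1), so it is deterministic, conserves
    localizations, and is monotone in ``max_distance`` (a larger radius never
    yields more molecules).
    """
    params = params or GroupingParams()
    out = []
    loc_mol = np.full(len(table.df), -1, dtype=np.int64)
    next_id = 0
    for ch in (Channel.CH1, Channel.CH2):
        sub = table.channel(ch)
        if len(sub) == 0:
            continue
        row_pos = sub.index.to_numpy()
        xy = sub[["x", "y"]].to_numpy(float)
        frames = sub["frame"].to_numpy(np.int64)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(params.max_distance, output_type="ndarray")
        if len(pairs):
            dt = np.abs(frames[pairs[:, 0]] - frames[pairs[:, 1]])
            pairs = pairs[dt <= params.frame_gap + 1]
        labels = _component_labels(xy, pairs, len(sub))
        for lab in np.unique(labels):
            mask = labels == lab
            out.append(
                (
                    next_id,
                    int(ch),
                    xy[mask, 0].mean(),
                    xy[mask, 1].mean(),
                    int(mask.sum()),
                    int(frames[mask].min()),
                    int(frames[mask].max()),
                )
            )
            loc_mol[row_pos[mask]] = next_id
            next_id += 1
    mol = pd.DataFrame(out, columns=MOLECULE_COLUMNS)
    if len(mol) == 0:
        mol = pd.DataFrame(
            {
                c: pd.Series(dtype=float if c in ("x", "y") else "int64")
                for c in MOLECULE_COLUMNS
            }
        )
    if return_labels:
        return mol, loc_mol
    return mol


def detect_clusters(
    molecules: pd.DataFrame,
    link_radius: float = DEFAULT_LINK_RADIUS_NM,
    min_molecules: int = DEFAULT_MIN_MOLECULES,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster molecules into candidate particles.

    Clusters are connected components of the cross-channel molecule graph with
    edges between molecules at most ``link_radius`` apart; only components
    with strictly more than ``min_molecules`` members are kept.

    Returns ``(clusters, cluster_id_per_molecule)`` where the second array is
    aligned with ``molecules`` rows and is -1 for molecules not in any kept
    cluster.  Cluster centre is the unweighted centroid of member molecules.
    """
    if link_radius <= 0:
        raise ValueError("link_radius must be > 0")
    n = len(molecules)
    assignment = np.full(n, -1, dtype=np.int64)
    if n == 0:
        clusters = pd.DataFrame(
            columns=[
                "cluster_id",
                "x",
                "y",
                "n_molecules_total",
                "n_ch1",
                "n_ch2",
                "n_localizations",
            ]
        )
        return clusters, assignment

    xy = molecules[["x", "y"]].to_numpy(float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    labels = _component_labels(xy, pairs, n)

    ch = molecules["channel"].to_numpy()
    nlocs = molecules["n_locs"].to_numpy()
    rows = []
    cid = 0
    for lab in np.unique(labels):
        mask = labels == lab
        size = int(mask.sum())
        if size <= min_molecules:
            continue
        rows.append(
            (
                cid,
                xy[mask, 0].mean(),
                xy[mask, 1].mean(),
                size,
                int((ch[mask] == int(Channel.CH1)).sum()),
                int((ch[mask] == int(Channel.CH2)).sum()),
                int(nlocs[mask].sum()),
            )
        )
        assignment[mask] = cid
        cid += 1
    clusters = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "x",
            "y",
            "n_molecules_total",
            "n_ch1",
            "n_ch2",
            "n_localizations",
        ],
    )
    return clusters, assignment
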