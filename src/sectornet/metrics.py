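"""Whole-network and per-member structural statistics for directed binary ties.

Definitions follow the classical sociometric conventions: density is the
fraction of ordered pairs with an arc; reciprocity is reported dyad-wise by
default (mutual dyads over connected dyads) with the arc-wise variant
available; centralization is Freeman's statistic on out-degree; betweenness
is raw (unnormalized) Freeman betweenness on directed geodesics, with
unreachable pairs contributing zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .model import Sociomatrix

ReciprocityMethod = str  # "dyad" | "arc"


def density(m: Sociomatrix) -> float:
    """Proportion of potential directed ties present: arcs / (n(n-1))."""
    if m.n < 2:
        raise ValueError("density requires at least 2 members")
    return m.arc_count / (m.n * (m.n - 1))


def degree_vectors(m: Sociomatrix) -> pd.DataFrame:
    """Per-member out-degree, in-degree and total (union) degree.

    Total degree counts distinct alters connected by an arc in either
    direction, so a mutual dyad contributes one to each endpoint, not two.
    """
    a = m.adjacency
    union = (a | a.T).astype(np.int64)
    return pd.DataFrame(
        {
            "member_id": list(m.member_ids),
            "out_degree": a.sum(axis=1).astype(np.int64),
            "in_degree": a.sum(axis=0).astype(np.int64),
            "total_degree": union.sum(axis=1),
        }
    )


def reciprocity(m: Sociomatrix, method: ReciprocityMethod = "dyad") -> float:
    """Extent to which reported ties are returned.

    ``dyad``: mutual dyads / dyads with at least one arc (default — matches
    the reading "reported by both members in a given pair").
    ``arc``: arcs lying in mutual dyads / all arcs.
    Undefined (NaN, with a warning) when the network has no arcs.
    """
    a = m.adjacency
    arcs = int(a.sum())
    if arcs == 0:
        warnings.warn("reciprocity undefined on an empty network", stacklevel=2)
        return math.nan
    mutual_arcs = int((a & a.T).sum())  # counts each mutual dyad twice
    if method == "dyad":
        connected_dyads = int((a | a.T).sum()) // 2
        return (mutual_arcs // 2) / connected_dyads
    if method == "arc":
        return mutual_arcs / arcs
    raise ValueError(f"unknown reciprocity method {method!r}")


def out_degree_centralization(m: Sociomatrix) -> float:
    """Freeman centralization on out-degree: sum(c_max - c_i) / (n-1)^2.

    Equals 1 for the out-star (one member reporting to everyone, nobody else
    reporting) and 0 for any out-regular network.
    """
    if m.n < 3:
        raise ValueError("centralization requires at least 3 members")
    out = m.adjacency.sum(axis=1)
    return float((out.max() - out).sum()) / (m.n - 1) ** 2


def betweenness(m: Sociomatrix, normalized: bool = False) -> np.ndarray:
    """Freeman betweenness per member on directed geodesics.

    Raw scores by default: b(v) = sum over ordered pairs (s, t) of the share
    of shortest directed s->t paths passing through v; unreachable pairs
    contribute zero.
    """
    g = m.to_digraph()
    scores = nx.betweenness_centrality(g, normalized=normalized)
    return np.array([scores[mid] for mid in m.member_ids], dtype=float)


@dataclass(frozen=True)
class NetworkSummary:
    """Wave-level structural profile (proportions in [0, 1], degrees in counts)."""

    wave: str
    n: int
    density: float
    out_degree_centralization: float
    reciprocity: float
    reciprocity_method: str
    mean_degree: float
    sd_degree: float
    mean_out_degree: float
    sd_out_degree: float
    mean_betweenness: float

    def to_record(self) -> dict:
        return asdict(self)


def summarize(
    m: Sociomatrix, reciprocity_method: ReciprocityMethod = "dyad"
) -> NetworkSummary:
    """All wave-level statistics in one record.

    Standard deviations are population SDs (ddof=0), the convention of the
    classical sociometric packages this mirrors.
    """
    deg = degree_vectors(m)
    btw = betweenness(m, normalized=False)
    return NetworkSummary(
        wave=m.wave,
        n=m.n,
        density=density(m),
        out_degree_centralization=out_degree_centralization(m),
        reciprocity=reciprocity(m, reciprocity_method),
        reciprocity_method=reciprocity_method,
        mean_degree=float(deg["total_degree"].mean()),
        sd_degree=float(deg["total_degree"].std(ddof=0)),
        mean_out_degree=float(deg["out_degree"].mean()),
        sd_out_degree=float(deg["out_degree"].std(ddof=0)),
        mean_betweenness=float(btw.mean()),
    )
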