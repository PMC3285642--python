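"""Sector-stratified (block) statistics and member-level intersectoral measures.

Two complementary views of cross-sector collaboration:

* block density — after union-symmetrizing the directed matrix (a tie counts
  regardless of which party reported it), the fraction of realized pairs
  within each sector and between each pair of sectors;
* block reciprocity — directional: of the arcs reported by members of sector
  G toward members of sector H, the share that were reciprocated.  The (G, H)
  and (H, G) cells legitimately differ.

Member-level statistics split each member's reported ties into intersectoral
(alter in another sector) and intrasectoral, with arc-based reciprocation
shares; a share is undefined (NaN) when the member reported no such ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SECTORS, MemberRoster, Sociomatrix, _check_alignment


@dataclass(frozen=True)
class BlockMatrix:
    """sector x sector matrix of densities or reciprocation shares.

    ``values`` entries lie in [0, 1] or are NaN where the cell is undefined
    (no within-group dyads for a singleton sector; no arcs for a reciprocity
    cell).  For ``kind="reciprocity"`` rows index the reporting sector and
    columns the target sector.
    """

    kind: str  # "density" | "reciprocity"
    sectors: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.sectors)
        if v.shape != (k, k):
            raise ValueError(f"values must be {k}x{k}, got {v.shape}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
                raise ValueError("block values must lie in [0, 1] or be NaN")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sectors", tuple(self.sectors))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sectors, columns=self.sectors)

    def cell(self, row_sector: str, col_sector: str) -> float:
        return float(
            self.values[self.sectors.index(row_sector), self.sectors.index(col_sector)]
        )


@dataclass(frozen=True)
class BlockChange:
    """Cellwise change between two waves, carrying both originals for reports."""

    kind: str
    sectors: tuple[str, ...]
    earlier: np.ndarray = field(repr=False)
    later: np.ndarray = field(repr=False)

    @property
    def delta(self) -> np.ndarray:
        return self.later - self.earlier


def _sector_indices(roster: MemberRoster) -> dict[str, np.ndarray]:
    sectors = roster.sectors
    return {s: np.flatnonzero(sectors == s) for s in SECTORS}


def block_density(m: Sociomatrix, roster: MemberRoster) -> BlockMatrix:
    """Within/between-sector tie density on the union-symmetrized network.

    A pair counts as tied if either member reported the connection.  The
    within-sector denominator is n_g(n_g-1)/2 unordered pairs (NaN for a
    singleton sector); the between-sector denominator is n_g * n_h pairs.
    The result is symmetric.
    """
    _check_alignment(m, roster)
    union = (m.adjacency | m.adjacency.T).astype(np.int64)
    groups = _sector_indices(roster)
    k = len(SECTORS)
    values = np.full((k, k), np.nan)
    for gi, g in enumerate(SECTORS):
        ig = groups[g]
        for hi, h in enumerate(SECTORS):
            ih = groups[h]
            if gi == hi:
                n_g = len(ig)
                if n_g < 2:
                    continue  # no within-group dyads: undefined
                ties = union[np.ix_(ig, ig)].sum() / 2
                values[gi, hi] = ties / (n_g * (n_g - 1) / 2)
            else:
                if len(ig) == 0 or len(ih) == 0:
                    continue
                ties = union[np.ix_(ig, ih)].sum()
                values[gi, hi] = ties / (len(ig) * len(ih))
    return BlockMatrix(kind="density", sectors=SECTORS, values=values)


def block_reciprocity(m: Sociomatrix, roster: MemberRoster) -> BlockMatrix:
    """Directional reciprocation shares by sector block.

    Cell (reporting=G, target=H) = reciprocated arcs from G-members to
    H-members / all arcs from G-members to H-members.  Within-group cells use
    the same rule on arcs among the group's members.  A cell with no arcs is
    NaN internally (reports may render it as 0; statistics never average it).
    """
    _check_alignment(m, roster)
    a = m.adjacency.astype(np.int64)
    mutual = a & a.T
    groups = _sector_indices(roster)
    k = len(SECTORS)
    values = np.full((k, k), np.nan)
    for gi, g in enumerate(SECTORS):
        ig = groups[g]
        if len(ig) == 0:
            continue
        for hi, h in enumerate(SECTORS):
            ih = groups[h]
            if len(ih) == 0:
                continue
            arcs = a[np.ix_(ig, ih)].sum()
            if arcs == 0:
                continue
            values[gi, hi] = mutual[np.ix_(ig, ih)].sum() / arcs
    return BlockMatrix(kind="reciprocity", sectors=SECTORS, values=values)


def member_intersectoral_stats(
    m: Sociomatrix, roster: MemberRoster
) -> pd.DataFrame:
    """Per-member split of reported ties by sector boundary.

    Columns: intersectoral_out_degree, intrasectoral_out_degree (their sum is
    the member's out-degree), and the arc-based reciprocation shares
    intersectoral_reciprocity / intrasectoral_reciprocity, NaN when the
    corresponding out-degree is zero.
    """
    _check_alignment(m, roster)
    a = m.adjacency.astype(np.int64)
    mutual = a & a.T
    same_sector = roster.sectors[:, None] == roster.sectors[None, :]
    np.fill_diagonal(same_sector, False)
    inter_out = (a * ~same_sector).sum(axis=1)
    intra_out = (a * same_sector).sum(axis=1)
    inter_recip_n = (mutual * ~same_sector).sum(axis=1)
    intra_recip_n = (mutual * same_sector).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inter_recip = np.where(inter_out > 0, inter_recip_n / inter_out, np.nan)
        intra_recip = np.where(intra_out > 0, intra_recip_n / intra_out, np.nan)
    return pd.DataFrame(
        {
            "member_id": list(m.member_ids),
            "sector": roster.sectors,
            "intersectoral_out_degree": inter_out,
            "intrasectoral_out_degree": intra_out,
            "intersectoral_reciprocity": inter_recip,
            "intrasectoral_reciprocity": intra_recip,
        }
    )


def block_change(later: BlockMatrix, earlier: BlockMatrix) -> BlockChange:
    """Cellwise later - earlier change matrix; undefined cells propagate NaN."""
    if later.kind != earlier.kind:
        raise ValueError(
            f"cannot difference a {later.kind} block against {earlier.kind}"
        )
    if later.sectors != earlier.sectors:
        raise ValueError("block matrices have different sector sets")
    return BlockChange(
        kind=later.kind,
        sectors=later.sectors,
        earlier=earlier.values.copy(),
        later=later.values.copy(),
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _fmt_pct(x: float, nan_as: str) -> str:
    if np.isnan(x):
        return nan_as
    return str(int(round(100 * x)))


def format_block_change(
    change: BlockChange, layout: str | None = None, nan_as: str = "n/a"
) -> pd.DataFrame:
    """Render a change matrix as "delta (early-late)" whole-percent strings.

    ``layout="upper"`` (default for density) blanks the redundant lower
    triangle of the symmetric density table; ``layout="full"`` (default for
    reciprocity) renders every cell with columns indexing the reporting
    sector, the printed convention for directional reciprocity tables.
    """
    if layout is None:
        layout = "upper" if change.kind == "density" else "full"
    early, late = change.earlier, change.later
    if change.kind == "reciprocity" and layout == "full":
        early, late = early.T, late.T  # columns = reporting sector
    k = len(change.sectors)
    cells = []
    for i in range(k):
        row = []
        for j in range(k):
            if layout == "upper" and j < i:
                row.append("")
                continue
            e, l = early[i, j], late[i, j]
            if np.isnan(e) or np.isnan(l):
                if change.kind == "reciprocity" and nan_as == "0":
                    row.append("0 (0–0)")
                else:
                    row.append(nan_as)
                continue
            delta = int(round(100 * l)) - int(round(100 * e))
            row.append(
                f"{delta} ({_fmt_pct(e, nan_as)}–{_fmt_pct(l, nan_as)})"
            )
        cells.append(row)
    return pd.DataFrame(cells, index=change.sectors, columns=change.sectors)
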