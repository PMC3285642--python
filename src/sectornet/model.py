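"""Domain types and file I/O for fixed-roster sociometric network data.

A sociometric study collects ties from every member of a pre-defined roster,
so the roster is the backbone object: it fixes the set of members, their
sector / city / tenure attributes, and the row-and-column order of every
adjacency matrix.  Ties are directed ("member i reported a connection to
member j") and binary.  Analysis is restricted to survey respondents; members
of the wider roster who did not respond are simply absent from these objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

#: The six fixed sector classifications for coalition members.
SECTORS: tuple[str, ...] = (
    "CBO/Coalition",
    "Researcher",
    "Philanthropic",
    "Policymaker",
    "Provider",
    "Public Sector",
)

#: The three communities the coalition operates in.
CITIES: tuple[str, ...] = ("Boston", "Lawrence", "Worcester")

ROSTER_COLUMNS = ("member_id", "label", "sector", "city", "original_member")

#: Binary outcome survey items, grouped by the index they feed.
OUTCOME_ITEM_GROUPS: dict[str, tuple[str, ...]] = {
    "community_activities": tuple(f"community_{k}" for k in range(1, 5)),
    "grants_publications": tuple(f"grants_{k}" for k in range(1, 4)),
    "policy_engagement": tuple(f"policy_{k}" for k in range(1, 3)),
}

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


class RosterError(ValueError):
    """Raised when a roster violates its invariants."""


class SociomatrixError(ValueError):
    """Raised when an adjacency matrix violates its invariants."""


def _as_bool(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise RosterError(f"cannot interpret {value!r} as a boolean in {where}")


@dataclass(frozen=True)
class MemberRoster:
    """The fixed list of network members with their grouping attributes.

    Row order is significant: it defines the row/column order of every
    sociomatrix and member-level statistic aligned to this roster.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
        if missing:
            raise RosterError(f"roster is missing columns {missing}")
        if len(df) == 0:
            raise RosterError("roster has no members")
        ids = df["member_id"].astype(str)
        if (ids.str.len() == 0).any():
            raise RosterError("roster contains an empty member_id")
        dup = ids[ids.duplicated()]
        if len(dup):
            raise RosterError(f"duplicate member_id(s): {sorted(set(dup))}")
        for row, sector in zip(ids, df["sector"]):
            if sector not in SECTORS:
                raise RosterError(
                    f"member {row!r} has unknown sector {sector!r}; "
                    f"expected one of {SECTORS}"
                )
        for row, city in zip(ids, df["city"]):
            if city not in CITIES:
                raise RosterError(
                    f"member {row!r} has unknown city {city!r}; "
                    f"expected one of {CITIES}"
                )
        clean = df.loc[:, list(ROSTER_COLUMNS)].copy()
        clean["member_id"] = ids
        clean["original_member"] = [
            _as_bool(v, f"original_member of {i}")
            for i, v in zip(ids, df["original_member"])
        ]
        clean.reset_index(drop=True, inplace=True)
        object.__setattr__(self, "table", clean)

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(self.table["member_id"])

    @property
    def sectors(self) -> np.ndarray:
        return self.table["sector"].to_numpy()

    @property
    def cities(self) -> np.ndarray:
        return self.table["city"].to_numpy()

    @property
    def original_member(self) -> np.ndarray:
        return self.table["original_member"].to_numpy(dtype=bool)

    def sector_counts(self) -> dict[str, int]:
        counts = self.table["sector"].value_counts()
        return {s: int(counts.get(s, 0)) for s in SECTORS}

    def city_counts(self) -> dict[str, int]:
        counts = self.table["city"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CITIES}

    def index_of(self, member_id: str) -> int:
        ids = self.member_ids
        try:
            return ids.index(member_id)
        except ValueError:
            raise RosterError(f"member_id {member_id!r} not on roster") from None

    def reordered(self, order: Iterable[int]) -> "MemberRoster":
        """Roster with rows permuted by positional ``order``."""
        idx = list(order)
        return MemberRoster(self.table.iloc[idx].reset_index(drop=True))


@dataclass(frozen=True)
class Sociomatrix:
    """Binary directed adjacency for one survey wave, aligned to a roster.

    Entry (i, j) = 1 means member i reported a connection to member j, so
    out-degree is the row sum.  The diagonal is structurally zero.
    """

    wave: str
    adjacency: np.ndarray = field(repr=False)
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise SociomatrixError(f"adjacency must be square, got shape {a.shape}")
        if a.shape[0] != len(self.member_ids):
            raise SociomatrixError(
                f"adjacency is {a.shape[0]}x{a.shape[0]} but roster has "
                f"{len(self.member_ids)} members"
            )
        if not np.isin(a, (0, 1)).all():
            raise SociomatrixError("adjacency entries must be 0 or 1")
        if np.diagonal(a).any():
            raise SociomatrixError("self-ties are not allowed (nonzero diagonal)")
        a = a.astype(np.int8)
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "member_ids", tuple(self.member_ids))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def arc_count(self) -> int:
        return int(self.adjacency.sum())

    def to_digraph(self, roster: MemberRoster | None = None) -> nx.DiGraph:
        """networkx DiGraph view; node attributes attached when a roster is given."""
        g = nx.DiGraph()
        g.add_nodes_from(self.member_ids)
        rows, cols = np.nonzero(self.adjacency)
        g.add_edges_from(
            (self.member_ids[i], self.member_ids[j]) for i, j in zip(rows, cols)
        )
        if roster is not None:
            _check_alignment(self, roster)
            for mid, sector, city, orig in zip(
                roster.member_ids, roster.sectors, roster.cities, roster.original_member
            ):
                g.nodes[mid].update(
                    sector=str(sector), city=str(city), original_member=bool(orig)
                )
        return g

    def reordered(self, order: Iterable[int]) -> "Sociomatrix":
        idx = np.asarray(list(order))
        return Sociomatrix(
            wave=self.wave,
            adjacency=self.adjacency[np.ix_(idx, idx)],
            member_ids=tuple(self.member_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class OutcomeItems:
    """Per-member binary survey responses feeding the three outcome indices."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        cols = [c for group in OUTCOME_ITEM_GROUPS.values() for c in group]
        missing = [c for c in ["member_id", *cols] if c not in df.columns]
        if missing:
            raise ValueError(f"outcome items missing columns {missing}")
        values = df[cols].to_numpy()
        if not np.isin(values, (0, 1)).all():
            bad = df.loc[~np.isin(values, (0, 1)).all(axis=1), "member_id"].tolist()
            raise ValueError(f"outcome items must be 0/1; offending member(s): {bad}")
        clean = df.loc[:, ["member_id", *cols]].copy()
        clean["member_id"] = clean["member_id"].astype(str)
        clean[cols] = clean[cols].astype(np.int64)
        clean.reset_index(drop=True, inplace=True)
        object.__setattr__(self, "table", clean)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(self.table["member_id"])


def _check_alignment(matrix: Sociomatrix, roster: MemberRoster) -> None:
    if matrix.member_ids != roster.member_ids:
        raise SociomatrixError(
            "sociomatrix member order does not match the roster order"
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_roster(path: str | Path) -> MemberRoster:
    """Read and validate a roster CSV (member_id,label,sector,city,original_member)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise RosterError(f"roster file {path} is empty") from None
    return MemberRoster(df)


def write_roster(roster: MemberRoster, path: str | Path) -> None:
    roster.table.to_csv(path, index=False)


def read_sociomatrix(
    path: str | Path,
    roster: MemberRoster,
    format: Literal["adjacency", "edgelist"] = "adjacency",
    wave: str = "wave",
) -> Sociomatrix:
    """Read a binary directed sociomatrix for the given roster.

    ``adjacency``: n x n CSV whose first column and header row are member ids.
    ``edgelist``: two-column CSV (source, target), one arc per row.

    Any nonzero adjacency value is coerced to 1 with a warning (the survey
    instrument is binary); self-loops and ids absent from the roster are hard
    errors, as is a dimension mismatch.
    """
    path = Path(path)
    if format == "adjacency":
        df = pd.read_csv(path, index_col=0)
        ids = tuple(str(i) for i in df.index)
        col_ids = tuple(str(c) for c in df.columns)
        if ids != col_ids:
            raise SociomatrixError(
                f"{path}: adjacency row and column ids disagree"
            )
        unknown = [i for i in ids if i not in roster.member_ids]
        if unknown:
            raise SociomatrixError(f"{path}: ids not on roster: {unknown}")
        if set(ids) != set(roster.member_ids) or len(ids) != roster.n:
            raise SociomatrixError(
                f"{path}: adjacency covers {len(ids)} members, roster has {roster.n}"
            )
        # Align file order to roster order.
        df = df.loc[list(roster.member_ids), list(roster.member_ids)]
        values = df.to_numpy(dtype=float)
        if np.diagonal(values).any():
            raise SociomatrixError(f"{path}: self-loop on the diagonal")
        nonbinary = (values != 0) & (values != 1)
        if nonbinary.any():
            warnings.warn(
                f"{path}: {int(nonbinary.sum())} non-binary entries coerced to 1",
                stacklevel=2,
            )
        adjacency = (values != 0).astype(np.int8)
    elif format == "edgelist":
        df = pd.read_csv(path, dtype=str)
        if not {"source", "target"}.issubset(df.columns):
            raise SociomatrixError(f"{path}: edge list needs source,target columns")
        index = {m: k for k, m in enumerate(roster.member_ids)}
        adjacency = np.zeros((roster.n, roster.n), dtype=np.int8)
        for _, row in df.iterrows():
            s, t = str(row["source"]), str(row["target"])
            if s not in index or t not in index:
                missing = [x for x in (s, t) if x not in index]
                raise SociomatrixError(f"{path}: ids not on roster: {missing}")
            if s == t:
                raise SociomatrixError(f"{path}: self-loop on {s!r}")
            adjacency[index[s], index[t]] = 1
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown sociomatrix format {format!r}")
    return Sociomatrix(wave=wave, adjacency=adjacency, member_ids=roster.member_ids)


def write_sociomatrix(matrix: Sociomatrix, path: str | Path) -> None:
    """Write the adjacency CSV layout ``read_sociomatrix`` consumes."""
    df = pd.DataFrame(
        matrix.adjacency, index=matrix.member_ids, columns=matrix.member_ids
    )
    df.to_csv(path)


def write_graphml(
    matrix: Sociomatrix, roster: MemberRoster, path: str | Path
) -> None:
    """Export the directed network with sector/city/tenure node attributes."""
    _check_alignment(matrix, roster)
    nx.write_graphml(matrix.to_digraph(roster), str(path))


def read_outcome_items(path: str | Path, roster: MemberRoster) -> OutcomeItems:
    """Read per-member binary outcome items, aligned to roster order."""
    df = pd.read_csv(path)
    items = OutcomeItems(df)
    if set(items.member_ids) != set(roster.member_ids):
        raise ValueError("outcome items do not cover exactly the roster members")
    order = [items.member_ids.index(m) for m in roster.member_ids]
    return OutcomeItems(items.table.iloc[order].reset_index(drop=True))


def write_outcome_items(items: OutcomeItems, path: str | Path) -> None:
    items.table.to_csv(path, index=False)


def response_rate(n_respondents: int, n_roster: int) -> float:
    """Survey response rate as a percentage of the full roster."""
    if n_roster <= 0 or n_respondents < 0 or n_respondents > n_roster:
        raise ValueError("need 0 <= n_respondents <= n_roster with n_roster > 0")
    return 100.0 * n_respondents / n_roster
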