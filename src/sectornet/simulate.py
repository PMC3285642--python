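"""Synthetic two-wave coalition networks with known generative structure.

The generator emulates a mid-sized health coalition observed at two time
points: ~38 members spread over six sectors and three cities, a directed
"who reported connecting with whom" matrix whose density roughly doubles
between inception and year 4 while reciprocation rises sharply, and
per-member binary outcome items driven by a linear model on intersectoral
connectivity.  Every stage is seeded, so downstream analyses are testable
end-to-end with no external data.

Generative model
----------------
For each unordered member pair, one member is chosen (fair coin) as the
potential *reporter*; the reporter names the other with probability given by
the sector-block target matrix, and a named tie is *confirmed* (the reverse
arc added) with probability ``reciprocity_boost``.  With base union-tie
probability p and boost r this yields directed density p(1+r)/2 and dyad
reciprocity exactly r at the later wave.  The inception wave is an
independent thinning of year-4 arcs with retention w, giving inception
density w*p(1+r)/2 and dyad reciprocity rw / ((1-r) + r(2-w)) — a three-
parameter model that pins both waves' density and reciprocity levels.

Optional member "activity" heterogeneity (``activity_dispersion`` > 0)
scales how many ties a member reports and, through the product of both
members' activity levels, how likely a named tie is confirmed.  Active
members then have both many reported ties and highly reciprocated ones,
coupling intersectoral out-degree with intersectoral reciprocity across
members (the situation in which the two focal predictors become too
collinear to enter one model).  At the homogeneous default (dispersion 0)
the mechanism is inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks
from .model import (
    CITIES,
    OUTCOME_ITEM_GROUPS,
    SECTORS,
    MemberRoster,
    OutcomeItems,
    Sociomatrix,
    write_outcome_items,
    write_roster,
    write_sociomatrix,
)

#: Sector head-counts of the reference 38-member coalition.
DEFAULT_SECTOR_COUNTS = {
    "CBO/Coalition": 11,
    "Researcher": 14,
    "Philanthropic": 1,
    "Policymaker": 2,
    "Provider": 4,
    "Public Sector": 6,
}
DEFAULT_CITY_COUNTS = {"Boston": 26, "Lawrence": 5, "Worcester": 7}
DEFAULT_N = 38
DEFAULT_ORIGINAL = 23

# Year-4 union-tie probabilities per sector block (within on the diagonal).
# Row/column order follows SECTORS.  The Philanthropic within-cell is a
# neutral placeholder: with a single philanthropic member it is never drawn.
DEFAULT_BLOCK_TARGETS = np.array(
    [
        [0.36, 0.35, 0.36, 0.41, 0.25, 0.50],
        [0.35, 0.66, 0.36, 0.46, 0.43, 0.44],
        [0.36, 0.36, 0.50, 0.50, 0.50, 0.17],
        [0.41, 0.46, 0.50, 1.00, 0.75, 0.58],
        [0.25, 0.43, 0.50, 0.75, 0.83, 0.50],
        [0.50, 0.44, 0.17, 0.58, 0.50, 0.67],
    ]
)


@dataclass(frozen=True)
class OutcomeModel:
    """Linear latent-score model behind the binary outcome items.

    latent_i = intercept + beta_focal * focal_i + city/tenure/sector effects
               + N(0, noise_sd^2)

    Each binary item switches on when the latent score crosses its cutpoint,
    so every index is a monotone step function of the latent score.
    """

    intercept: float = 1.0
    beta_focal: float = 0.15
    focal: str = "intersectoral_out_degree"  # or "intersectoral_reciprocity"
    city_effects: dict[str, float] = field(
        default_factory=lambda: {"Lawrence": -0.3, "Worcester": -0.2}
    )
    original_effect: float = 0.5
    sector_effects: dict[str, float] = field(
        default_factory=lambda: {"CBO/Coalition": 0.3, "Public Sector": 0.2}
    )
    noise_sd: float = 1.0
    # Item cutpoints per index, calibrated so default index means sit near
    # the reference coalition's (about 2.0, 2.3 and 1.1).
    cutpoints: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "community_activities": (1.2, 2.2, 3.0, 4.0),
            "grants_publications": (0.6, 1.4, 2.4),
            "policy_engagement": (1.8, 3.0),
        }
    )

    @staticmethod
    def for_focal(focal: str) -> "OutcomeModel":
        """Defaults on the natural scale of each focal predictor."""
        if focal == "intersectoral_out_degree":
            return OutcomeModel()
        if focal == "intersectoral_reciprocity":
            return OutcomeModel(beta_focal=3.5, focal=focal)
        raise ValueError(f"unknown focal statistic {focal!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic coalition, with study-scale defaults."""

    n_members: int = DEFAULT_N
    sector_proportions: tuple[float, ...] = tuple(
        DEFAULT_SECTOR_COUNTS[s] / DEFAULT_N for s in SECTORS
    )
    city_proportions: tuple[float, ...] = tuple(
        DEFAULT_CITY_COUNTS[c] / DEFAULT_N for c in CITIES
    )
    original_fraction: float = DEFAULT_ORIGINAL / DEFAULT_N
    block_density_targets: np.ndarray = field(
        default_factory=lambda: DEFAULT_BLOCK_TARGETS.copy()
    )
    reciprocity_boost: float = 0.54
    wave1_retention: float = 16 / 35
    activity_dispersion: float = 0.0
    nested_waves: bool = True
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("need at least 2 members")
        for name, probs, k in (
            ("sector_proportions", self.sector_proportions, len(SECTORS)),
            ("city_proportions", self.city_proportions, len(CITIES)),
        ):
            probs = tuple(float(p) for p in probs)
            if len(probs) != k:
                raise ValueError(f"{name} must have {k} entries")
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
            object.__setattr__(self, name, probs)
        for name in ("original_fraction", "reciprocity_boost", "wave1_retention"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        targets = np.asarray(self.block_density_targets, dtype=float)
        if targets.shape != (len(SECTORS), len(SECTORS)):
            raise ValueError("block_density_targets must be 6x6")
        if (targets < 0).any() or (targets > 1).any():
            raise ValueError("block_density_targets must lie in [0, 1]")
        if not np.allclose(targets, targets.T):
            raise ValueError("block_density_targets must be symmetric")
        targets.setflags(write=False)
        object.__setattr__(self, "block_density_targets", targets)
        if self.activity_dispersion < 0 or self.activity_dispersion > 1:
            raise ValueError("activity_dispersion must lie in [0, 1]")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _largest_remainder(proportions: tuple[float, ...], n: int) -> np.ndarray:
    """Deterministic rounded allocation of n members to levels."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_roster(cfg: GeneratorConfig, seed: int | None = None) -> MemberRoster:
    """Roster with deterministic level counts and seed-shuffled assignment."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_members
    sector_counts = _largest_remainder(cfg.sector_proportions, n)
    city_counts = _largest_remainder(cfg.city_proportions, n)
    sectors = np.repeat(np.array(SECTORS, dtype=object), sector_counts)
    cities = np.repeat(np.array(CITIES, dtype=object), city_counts)
    original = np.zeros(n, dtype=bool)
    original[: int(np.floor(cfg.original_fraction * n))] = True
    rng.shuffle(sectors)
    rng.shuffle(cities)
    rng.shuffle(original)
    width = len(str(n))
    table = pd.DataFrame(
        {
            "member_id": [f"m{k + 1:0{width}d}" for k in range(n)],
            "label": [f"{sectors[k]} member {k + 1}" for k in range(n)],
            "sector": sectors,
            "city": cities,
            "original_member": original,
        }
    )
    return MemberRoster(table)


@dataclass(frozen=True)
class WavePair:
    """Two nested survey waves over one roster."""

    year4: Sociomatrix
    inception: Sociomatrix


def _member_activity(cfg: GeneratorConfig, n: int, rng) -> np.ndarray:
    if cfg.activity_dispersion == 0:
        return np.ones(n)
    return 1.0 + cfg.activity_dispersion * (2 * rng.random(n) - 1)


def generate_network(
    roster: MemberRoster, cfg: GeneratorConfig, seed: int | None = None
) -> WavePair:
    """Sample the year-4 sociomatrix and its nested inception thinning.

    Per unordered pair: a fair coin picks the reporter; the reporter names
    the pair's tie with the block target probability (scaled by its activity
    level), and a named tie is confirmed by the other member with
    probability ``reciprocity_boost`` (scaled likewise).  Inception keeps
    each year-4 arc independently with probability ``wave1_retention``
    (guaranteeing inception arcs are a subset of year-4 arcs) unless
    ``nested_waves`` is off, in which case inception is drawn independently
    from retention-scaled targets.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = roster.n
    sector_idx = np.array([SECTORS.index(s) for s in roster.sectors])
    activity = _member_activity(cfg, n, rng)
    iu, ju = np.triu_indices(n, k=1)
    pair_target = cfg.block_density_targets[sector_idx[iu], sector_idx[ju]]

    def draw_wave(targets: np.ndarray) -> np.ndarray:
        reporter_is_i = rng.random(len(iu)) < 0.5
        rep = np.where(reporter_is_i, iu, ju)
        other = np.where(reporter_is_i, ju, iu)
        p_report = np.clip(targets * activity[rep], 0, 1)
        named = rng.random(len(iu)) < p_report
        p_confirm = np.clip(
            cfg.reciprocity_boost * activity[rep] * activity[other], 0, 1
        )
        confirmed = named & (rng.random(len(iu)) < p_confirm)
        a = np.zeros((n, n), dtype=np.int8)
        a[rep[named], other[named]] = 1
        a[other[confirmed], rep[confirmed]] = 1
        return a

    a4 = draw_wave(pair_target)
    if cfg.nested_waves:
        keep = rng.random(a4.shape) < cfg.wave1_retention
        a1 = (a4.astype(bool) & keep).astype(np.int8)
    else:
        a1 = draw_wave(pair_target * cfg.wave1_retention)
    ids = roster.member_ids
    return WavePair(
        year4=Sociomatrix(wave="year4", adjacency=a4, member_ids=ids),
        inception=Sociomatrix(wave="inception", adjacency=a1, member_ids=ids),
    )


def expected_density(cfg: GeneratorConfig, roster: MemberRoster) -> float:
    """Closed-form expected directed density of the year-4 wave.

    Valid at the homogeneous-activity default (``activity_dispersion`` = 0):
    each unordered pair contributes p(1 + r) expected arcs out of 2.
    """
    if cfg.activity_dispersion != 0:
        raise ValueError("closed form assumes homogeneous activity")
    sector_idx = np.array([SECTORS.index(s) for s in roster.sectors])
    iu, ju = np.triu_indices(roster.n, k=1)
    p = cfg.block_density_targets[sector_idx[iu], sector_idx[ju]]
    expected_arcs = float((p * (1 + cfg.reciprocity_boost)).sum())
    return expected_arcs / (roster.n * (roster.n - 1))


@dataclass(frozen=True)
class SyntheticOutcomes:
    """Generated items plus the ground truth behind them, for recovery tests."""

    items: OutcomeItems
    latent: np.ndarray = field(repr=False)
    focal_values: np.ndarray = field(repr=False)
    model: OutcomeModel


def focal_statistic(
    roster: MemberRoster, m: Sociomatrix, which: str
) -> np.ndarray:
    """Member-level focal predictor; undefined reciprocity shares coded 0.

    A member who reported no intersectoral ties has no reciprocated ones, so
    its reciprocity share enters regressions as 0 rather than NaN.
    """
    stats = blocks.member_intersectoral_stats(m, roster)
    if which not in ("intersectoral_out_degree", "intersectoral_reciprocity"):
        raise ValueError(f"unknown focal statistic {which!r}")
    return np.nan_to_num(stats[which].to_numpy(dtype=float), nan=0.0)


def generate_outcomes(
    roster: MemberRoster,
    m: Sociomatrix,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> SyntheticOutcomes:
    """Draw binary outcome items from the latent linear model."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    om = cfg.outcome_model
    focal = focal_statistic(roster, m, om.focal)
    latent = om.intercept + om.beta_focal * focal
    for city, eff in om.city_effects.items():
        latent = latent + eff * (roster.cities == city)
    latent = latent + om.original_effect * roster.original_member
    for sector, eff in om.sector_effects.items():
        latent = latent + eff * (roster.sectors == sector)
    if om.noise_sd > 0:
        latent = latent + rng.normal(0.0, om.noise_sd, roster.n)
    data: dict[str, object] = {"member_id": list(roster.member_ids)}
    for index_name, cols in OUTCOME_ITEM_GROUPS.items():
        cuts = om.cutpoints[index_name]
        if len(cuts) != len(cols):
            raise ValueError(f"{index_name} needs {len(cols)} cutpoints")
        for cut, col in zip(cuts, cols):
            data[col] = (latent >= cut).astype(int)
    return SyntheticOutcomes(
        items=OutcomeItems(pd.DataFrame(data)),
        latent=np.asarray(latent, dtype=float),
        focal_values=focal,
        model=om,
    )


@dataclass(frozen=True)
class SyntheticDataset:
    """One complete synthetic study: roster, two waves, outcome items."""

    roster: MemberRoster
    waves: WavePair
    outcomes: SyntheticOutcomes
    config: GeneratorConfig
    seed: int


def generate_dataset(
    cfg: GeneratorConfig, seed: int | None = None
) -> SyntheticDataset:
    """Roster, both waves, and outcomes from one master seed."""
    master = cfg.seed if seed is None else seed
    s_roster, s_net, s_out = np.random.SeedSequence(master).spawn(3)
    roster = generate_roster(cfg, seed=s_roster)
    waves = generate_network(roster, cfg, seed=s_net)
    outcomes = generate_outcomes(roster, waves.year4, cfg, seed=s_out)
    return SyntheticDataset(
        roster=roster, waves=waves, outcomes=outcomes, config=cfg, seed=master
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the CSVs the readers consume; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.csv",
        "inception": out / "sociomatrix_inception.csv",
        "year4": out / "sociomatrix_year4.csv",
        "outcome_items": out / "outcome_items.csv",
    }
    write_roster(ds.roster, paths["roster"])
    write_sociomatrix(ds.waves.inception, paths["inception"])
    write_sociomatrix(ds.waves.year4, paths["year4"])
    write_outcome_items(ds.outcomes.items, paths["outcome_items"])
    return paths
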