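"""Config-driven end-to-end analysis of a two-wave coalition network.

One call produces everything a coalition evaluation reports: wave-level
structure summaries, sector-block density and reciprocity matrices with
change tables, member-level intersectoral statistics, outcome index
summaries, and the six permutation regressions (two focal predictors x
three outcomes).  Inputs are either CSV paths or a synthetic-generator
block; every run is fully determined by (config, seed) and the emitted
report carries the metadata needed to reproduce itself byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import blocks, metrics, outcomes, permreg, simulate
from .model import (
    MemberRoster,
    OutcomeItems,
    Sociomatrix,
    read_outcome_items,
    read_roster,
    read_sociomatrix,
    write_graphml,
)

__version__ = "0.1.0"

logger = logging.getLogger("sectornet")

FOCAL_PREDICTORS = ("intersectoral_out_degree", "intersectoral_reciprocity")


class ConfigError(ValueError):
    """Raised for malformed analysis configurations."""


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one analysis run computed, plus the metadata to re-run it."""

    summaries: dict[str, metrics.NetworkSummary]
    block_density: dict[str, blocks.BlockMatrix]
    block_reciprocity: dict[str, blocks.BlockMatrix]
    density_change: blocks.BlockChange
    reciprocity_change: blocks.BlockChange
    member_stats: dict[str, pd.DataFrame] = field(repr=False)
    outcome_indices: pd.DataFrame = field(repr=False)
    outcome_summary: pd.DataFrame = field(repr=False)
    collinearity: permreg.CollinearityReport
    regressions: dict[str, dict[str, permreg.PermRegressionResult]]
    metadata: dict[str, Any]

    def to_json_dict(self) -> dict:
        def blockdict(bm: blocks.BlockMatrix) -> dict:
            return {
                "kind": bm.kind,
                "sectors": list(bm.sectors),
                "values": _nanlist(bm.values),
            }

        return {
            "metadata": self.metadata,
            "network_summaries": {
                w: s.to_record() for w, s in self.summaries.items()
            },
            "block_density": {w: blockdict(b) for w, b in self.block_density.items()},
            "block_reciprocity": {
                w: blockdict(b) for w, b in self.block_reciprocity.items()
            },
            "density_change": _nanlist(self.density_change.delta),
            "reciprocity_change": _nanlist(self.reciprocity_change.delta),
            "member_stats": {
                w: _frame_records(df) for w, df in self.member_stats.items()
            },
            "outcome_indices": _frame_records(self.outcome_indices),
            "outcome_summary": _frame_records(self.outcome_summary),
            "collinearity": {
                "threshold": self.collinearity.threshold,
                "correlations": _frame_records(
                    self.collinearity.correlations.reset_index(names="predictor")
                ),
                "flagged": [list(f) for f in self.collinearity.flagged],
                "excluded_zero_variance": list(
                    self.collinearity.excluded_zero_variance
                ),
            },
            "regressions": {
                focal: {out: res.to_record() for out, res in by_outcome.items()}
                for focal, by_outcome in self.regressions.items()
            },
        }


def _nanlist(a: np.ndarray) -> list:
    return [[None if np.isnan(x) else float(x) for x in row] for row in np.asarray(a, float)]


def _frame_records(df: pd.DataFrame) -> list[dict]:
    records = []
    for rec in df.to_dict(orient="records"):
        clean = {}
        for k, v in rec.items():
            if isinstance(v, (np.floating, float)):
                clean[k] = None if np.isnan(v) else float(v)
            elif isinstance(v, (np.integer, int)):
                clean[k] = int(v)
            elif isinstance(v, (np.bool_, bool)):
                clean[k] = bool(v)
            else:
                clean[k] = v
        records.append(clean)
    return records


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _build_generator_config(block: dict) -> simulate.GeneratorConfig:
    block = dict(block or {})
    om_block = block.pop("outcome_model", None)
    kwargs: dict[str, Any] = {}
    if om_block is not None:
        focal = om_block.pop("focal", "intersectoral_out_degree")
        om = simulate.OutcomeModel.for_focal(focal)
        from dataclasses import replace

        kwargs["outcome_model"] = replace(om, **om_block)
    try:
        return simulate.GeneratorConfig(**block, **kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad synthetic block: {exc}") from None


def _load_inputs(
    config: dict, seed: int
) -> tuple[MemberRoster, Sociomatrix, Sociomatrix, OutcomeItems]:
    if "inputs" in config and "synthetic" in config:
        raise ConfigError("config must give either 'inputs' or 'synthetic', not both")
    if "inputs" in config:
        paths = config["inputs"]
        needed = {"roster", "inception", "year4", "outcome_items"}
        missing = needed - set(paths)
        if missing:
            raise ConfigError(f"inputs block missing paths: {sorted(missing)}")
        fmt = paths.get("format", "adjacency")
        roster = read_roster(paths["roster"])
        inception = read_sociomatrix(
            paths["inception"], roster, format=fmt, wave="inception"
        )
        year4 = read_sociomatrix(paths["year4"], roster, format=fmt, wave="year4")
        items = read_outcome_items(paths["outcome_items"], roster)
        return roster, inception, year4, items
    if "synthetic" in config:
        gen_cfg = _build_generator_config(config["synthetic"])
        ds = simulate.generate_dataset(gen_cfg, seed=seed)
        return ds.roster, ds.waves.inception, ds.waves.year4, ds.outcomes.items
    raise ConfigError("config needs an 'inputs' or a 'synthetic' block")


def run_analysis(
    config: dict, out_dir: str | Path | None = None, seed: int | None = None
) -> AnalysisReport:
    """Run the full analysis described by ``config``; optionally write reports.

    ``config`` keys: ``inputs`` (CSV paths) or ``synthetic`` (generator
    overrides), and an optional ``params`` block with n_perms, seed,
    reciprocity_method, city_reference, sector_reference,
    collinearity_threshold, permutation_scheme.
    """
    params = dict(config.get("params") or {})
    if seed is None:
        seed = int(params.get("seed", 0))
    n_perms = int(params.get("n_perms", 10_000))
    recip_method = params.get("reciprocity_method", "dyad")
    scheme = params.get("permutation_scheme", "y")
    city_ref = params.get("city_reference", "Boston")
    sector_ref = params.get("sector_reference", "Researcher")
    threshold = float(params.get("collinearity_threshold", 0.70))

    logger.info(
        "run: seed=%s n_perms=%s reciprocity=%s scheme=%s refs=(%s, %s) "
        "collinearity_threshold=%s",
        seed, n_perms, recip_method, scheme, city_ref, sector_ref, threshold,
    )
    roster, inception, year4, items = _load_inputs(config, seed)

    waves = {"inception": inception, "year4": year4}
    summaries = {w: metrics.summarize(m, recip_method) for w, m in waves.items()}
    bden = {w: blocks.block_density(m, roster) for w, m in waves.items()}
    brec = {w: blocks.block_reciprocity(m, roster) for w, m in waves.items()}
    dchange = blocks.block_change(bden["year4"], bden["inception"])
    rchange = blocks.block_change(brec["year4"], brec["inception"])
    mstats = {
        w: blocks.member_intersectoral_stats(m, roster) for w, m in waves.items()
    }
    indices = outcomes.build_indices(items)
    osummary = outcomes.summarize_outcomes(indices)

    # Candidate predictors for collinearity screening (year 4, undefined -> 0).
    y4 = mstats["year4"]
    candidates = {
        name: np.nan_to_num(y4[name].to_numpy(dtype=float), nan=0.0)
        for name in (
            "intersectoral_out_degree",
            "intrasectoral_out_degree",
            "intersectoral_reciprocity",
            "intrasectoral_reciprocity",
        )
    }
    screen = permreg.collinearity_screen(candidates, threshold=threshold)
    for a, b, r in screen.flagged:
        logger.info("collinearity: %s vs %s |r|=%.2f flagged", a, b, r)

    regressions: dict[str, dict[str, permreg.PermRegressionResult]] = {}
    model_index = 0
    for focal_name in FOCAL_PREDICTORS:
        focal = candidates[focal_name]
        X = permreg.build_design(
            roster,
            focal,
            focal_name=focal_name,
            city_reference=city_ref,
            sector_reference=sector_ref,
        )
        by_outcome = {}
        for outcome_name in outcomes.INDEX_NAMES:
            y = indices[outcome_name].to_numpy(dtype=float)
            model_index += 1
            model_seed = (seed * 31 + model_index) % (2**31 - 1)
            by_outcome[outcome_name] = permreg.permutation_pvalues(
                X,
                y,
                n_perms=n_perms,
                seed=model_seed,
                scheme=scheme,
                focal=focal_name,
            )
        regressions[focal_name] = by_outcome

    metadata = {
        "software": "sectornet",
        "version": __version__,
        "seed": seed,
        "n_perms": n_perms,
        "reciprocity_method": recip_method,
        "permutation_scheme": scheme,
        "city_reference": city_ref,
        "sector_reference": sector_ref,
        "collinearity_threshold": threshold,
        "n_members": roster.n,
        "input_mode": "inputs" if "inputs" in config else "synthetic",
    }
    report = AnalysisReport(
        summaries=summaries,
        block_density=bden,
        block_reciprocity=brec,
        density_change=dchange,
        reciprocity_change=rchange,
        member_stats=mstats,
        outcome_indices=indices,
        outcome_summary=osummary,
        collinearity=screen,
        regressions=regressions,
        metadata=metadata,
    )
    if out_dir is not None:
        write_report(report, roster, waves, out_dir)
    return report


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def regression_table(report: AnalysisReport) -> pd.DataFrame:
    """Two-panel regression table: per focal model, intercept / focal beta / R^2
    for each of the three outcomes, with significance markers on the focal row."""
    rows = []
    for k, (focal, by_outcome) in enumerate(report.regressions.items(), start=1):
        for stat in ("intercept", focal, "r_squared"):
            row: dict[str, Any] = {"model": f"Model {k}", "term": stat}
            for outcome_name, res in by_outcome.items():
                if stat == "r_squared":
                    row[outcome_name] = f"{res.r_squared:.2f}"
                else:
                    beta = res.coef[stat]
                    marker = res.significance_marker(stat) if stat == focal else ""
                    row[outcome_name] = f"{beta:.2f}{marker}"
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    report: AnalysisReport,
    roster: MemberRoster,
    waves: dict[str, Sociomatrix],
    out_dir: str | Path,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = pd.DataFrame([s.to_record() for s in report.summaries.values()])
    paths["summary"] = out / "summary.csv"
    summary.to_csv(paths["summary"], index=False)

    paths["table2_density"] = out / "table2_density.csv"
    blocks.format_block_change(report.density_change, layout="upper").to_csv(
        paths["table2_density"]
    )
    paths["table3_reciprocity"] = out / "table3_reciprocity.csv"
    blocks.format_block_change(
        report.reciprocity_change, layout="full", nan_as="0"
    ).to_csv(paths["table3_reciprocity"])

    paths["table4_regressions"] = out / "table4_regressions.csv"
    regression_table(report).to_csv(paths["table4_regressions"], index=False)

    members = report.member_stats["year4"].merge(
        report.outcome_indices, on="member_id"
    )
    paths["members"] = out / "members.csv"
    members.to_csv(paths["members"], index=False)

    paths["report"] = out / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["graphml_year4"] = out / "network_year4.graphml"
    write_graphml(waves["year4"], roster, paths["graphml_year4"])

    paths["log"] = out / "run.log"
    with open(paths["log"], "w") as fh:
        for key, value in report.metadata.items():
            fh.write(f"{key}: {value}\n")
    return paths


# ---------------------------------------------------------------------------
# Network layout (force-directed map export)
# ---------------------------------------------------------------------------


def layout_spring(m: Sociomatrix, seed: int = 0) -> pd.DataFrame:
    """Seeded force-directed 2-D coordinates for a network map.

    Spring embedding places highly connected members centrally and directly
    connected members near one another; the exported node size field is the
    member's total (union) degree, the conventional sizing for such maps.
    """
    g = nx.Graph()
    g.add_nodes_from(m.member_ids)
    union = m.adjacency | m.adjacency.T
    rows, cols = np.nonzero(np.triu(union))
    g.add_edges_from(
        (m.member_ids[i], m.member_ids[j]) for i, j in zip(rows, cols)
    )
    pos = nx.spring_layout(g, seed=seed)
    degrees = metrics.degree_vectors(m)
    return pd.DataFrame(
        {
            "member_id": list(m.member_ids),
            "x": [float(pos[mid][0]) for mid in m.member_ids],
            "y": [float(pos[mid][1]) for mid in m.member_ids],
            "degree": degrees["total_degree"].to_numpy(),
        }
    )
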