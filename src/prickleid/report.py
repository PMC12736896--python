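"""Pipeline driver and report rendering.

``run_pipeline`` wires the stages together — load or simulate a reference
collection, estimate likelihoods, classify/attribute each observation under
every prior scenario, summarize prior sensitivity — and writes CSV and JSON
reports plus a provenance log sufficient to reproduce the run.  Reports are
pure functions of (config, seed): rerunning the same config yields
byte-identical JSON.

``render_posterior_table`` lays results out in the conventional published
form: one row per taxon; per scenario a prior column and a posterior column
per observed type; half-up rounding at the requested precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .bayes import PosteriorResult, PriorScenario, attribute, sensitivity_report
from .errors import PrickleidError, ValidationError
from .likelihood import LikelihoodTable, estimate_likelihoods
from .morphometry import DEFAULT_PROTOTYPES, classify_prickle
from .reference import (
    PrickleObservation,
    ReferenceCollection,
    read_observations_csv,
    read_reference_csv,
)
from .simulate import SimulationConfig, generate_reference

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_posterior_table", "round_half_up"]

log = logging.getLogger("prickleid")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at fixed decimals (published-table style:
    0.125 -> 0.13), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """One pipeline run: exactly one reference source, >=1 prior scenario."""

    scenarios: list[PriorScenario]
    reference_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    observations_path: str | Path | None = None
    observations: list[PrickleObservation] = field(default_factory=list)
    smoothing_alpha: float = 0.0
    organ_filter: str = "both"
    out_dir: str | Path | None = None
    seed: int = 0
    decimals: int = 2

    def __post_init__(self):
        if (self.reference_path is None) == (self.simulation is None):
            raise ValidationError(
                "exactly one of reference_path / simulation must be given"
            )
        if not self.scenarios:
            raise ValidationError("at least one prior scenario is required")


@dataclass
class ReportBundle:
    """Everything a run produced, before/after serialization."""

    table: LikelihoodTable
    results: dict[str, dict[str, PosteriorResult]]  # obs id -> scenario -> result
    sensitivity: dict[str, object]
    provenance: dict


def _load_reference(config: RunConfig) -> ReferenceCollection:
    if config.reference_path is not None:
        return read_reference_csv(config.reference_path)
    sim = config.simulation
    if sim.seed != config.seed:
        sim = SimulationConfig(
            profiles=sim.profiles,
            n_fragments_per_taxon=sim.n_fragments_per_taxon,
            fragment_length_range_cm=sim.fragment_length_range_cm,
            seed=config.seed,
        )
    return generate_reference(sim)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full attribution pipeline for one configuration.

    Stage failures abort with the stage name prefixed to the error.  When
    ``out_dir`` is set, writes ``posteriors.csv``, ``report.json`` and
    ``run.log`` there.
    """

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PrickleidError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    coll = stage("reference", _load_reference, config)
    log.info("reference collection: %d records, %d taxa", len(coll), len(coll.taxa))
    table = stage(
        "likelihood",
        estimate_likelihoods,
        coll,
        smoothing_alpha=config.smoothing_alpha,
        organ_filter=config.organ_filter,
    )

    if config.observations_path is not None:
        observations = stage("observations", read_observations_csv, config.observations_path)
    else:
        observations = list(config.observations)

    results: dict[str, dict[str, PosteriorResult]] = {}
    for obs in observations:
        x = classify_prickle(obs, DEFAULT_PROTOTYPES)
        results[obs.id] = {
            sc.name: stage("attribute", attribute, x, table, sc)
            for sc in config.scenarios
        }

    sensitivity = {}
    if len(config.scenarios) >= 2:
        for obs in observations:
            x = classify_prickle(obs, DEFAULT_PROTOTYPES)
            rep = stage("sensitivity", sensitivity_report, x, table, config.scenarios)
            sensitivity[obs.id] = {
                "observed_type": rep.observed_type.value,
                "map_changed": rep.map_changed,
                "max_shift": rep.max_shift,
                "shifts": {t: rep.shifts[t] for t in sorted(rep.shifts)},
            }

    provenance = {
        "seed": config.seed,
        "smoothing_alpha": config.smoothing_alpha,
        "organ_filter": config.organ_filter,
        "reference": str(config.reference_path)
        if config.reference_path is not None
        else {
            "simulated": True,
            "n_fragments_per_taxon": config.simulation.n_fragments_per_taxon,
            "fragment_length_range_cm": list(
                config.simulation.fragment_length_range_cm
            ),
            "taxa": [p.taxon for p in config.simulation.profiles],
        },
        "scenarios": {
            sc.name: {t: sc.weights[t] for t in sc.taxa} for sc in config.scenarios
        },
        "n_observations": len(observations),
    }
    bundle = ReportBundle(
        table=table, results=results, sensitivity=sensitivity, provenance=provenance
    )
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: ReportBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for obs_id, per_scenario in bundle.results.items():
        for sc_name, res in per_scenario.items():
            for taxon, p in res.posteriors.items():
                rows.append(
                    {
                        "observation": obs_id,
                        "scenario": sc_name,
                        "observed_type": res.observed_type.value,
                        "taxon": taxon,
                        "posterior": p,
                        "map": taxon == res.map_taxon,
                    }
                )
    pd.DataFrame(
        rows,
        columns=["observation", "scenario", "observed_type", "taxon", "posterior", "map"],
    ).to_csv(out / "posteriors.csv", index=False, lineterminator="\n")

    doc = {
        "provenance": bundle.provenance,
        "likelihoods": bundle.table.to_json(),
        "posteriors": {
            obs_id: {
                sc: {
                    "observed_type": r.observed_type.value,
                    "marginal": r.marginal,
                    "map_taxon": r.map_taxon,
                    "ties": list(r.ties),
                    "posteriors": {t: r.posteriors[t] for t in r.posteriors},
                }
                for sc, r in per_scenario.items()
            }
            for obs_id, per_scenario in bundle.results.items()
        },
        "sensitivity": bundle.sensitivity,
    }
    (out / "report.json").write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "run.log").write_text(
        "\n".join(f"{k} = {v}" for k, v in sorted(bundle.provenance.items(), key=lambda kv: kv[0]))
        + "\n",
        encoding="utf-8",
    )


def render_posterior_table(
    results: list[PosteriorResult], decimals: int = 2
) -> str:
    """Format posterior results as a taxa-by-scenario text table.

    Results are grouped by scenario (column blocks in first-appearance
    order); within a block there is the scenario's prior-implied posterior
    column per observed type, labelled ``p(Taxon|T1)`` etc.  All results
    must share one taxon list.
    """
    if not results:
        raise ValidationError("no results to render")
    taxa = list(results[0].posteriors)
    for r in results[1:]:
        if list(r.posteriors) != taxa:
            raise ValidationError("results do not share a taxon list")

    blocks: dict[str, list[PosteriorResult]] = {}
    for r in results:
        blocks.setdefault(r.scenario, []).append(r)

    headers = ["Taxa"]
    for sc, rs in blocks.items():
        for r in rs:
            headers.append(f"{sc}: p(Taxon|{r.observed_type.value})")
    widths = [max(len(t) for t in taxa + ["Taxa"])]
    body_cols: list[list[str]] = []
    for sc, rs in blocks.items():
        for r in rs:
            body_cols.append(
                [f"{round_half_up(r.posteriors[t], decimals):.{decimals}f}" for t in taxa]
            )
    widths += [max(len(h), decimals + 2) for h in headers[1:]]

    def fmt(cells):
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()

    lines = [fmt(headers), fmt(["-" * w for w in widths])]
    for i, taxon in enumerate(taxa):
        lines.append(fmt([taxon] + [col[i] for col in body_cols]))
    return "\n".join(lines)
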