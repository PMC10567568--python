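"""CSV dialects, pipeline configuration and the stage-chaining runner.

All tables are plain UTF-8 CSV with a header row, mirroring the tabular
exports of the upstream Red List:

* assessments — ``species_id, binomial, order, realms`` (semicolon-
  separated realm codes), one ``cat_<year>`` column per epoch (values
  ``LC|NT|VU|EN|CR|CR(PE)|EW|EX|DD``, case-insensitive), the five
  breeding-code columns (``yes|no|unknown``) and ``unmapped`` (0|1);
* ledger — ``species_id, epoch_from, epoch_to, state_at_from,
  primary_driver, codriver_count, conservation_driven``;
* threats — ``species_id, code, timing, named_agent, major``;
* incidence — ``species_id, cell_col, cell_row``.

Parse failures are collected with row numbers and raised together, so one
error report covers a whole malformed file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import backcast as _backcast
from . import rli as _rli
from . import spatial as _spatial
from . import stats as _stats
from . import threats as _threats
from .backcast import (
    ChangeDirection,
    GenuineChangeDeclaration,
    PrimaryDriver,
    changes_for_records,
    tabulate_changes,
)
from .model import (
    AssessmentRecord,
    BreedingCodes,
    DEFAULT_EPOCHS,
    Realm,
    TaxonomicOrder,
    TriState,
    format_category,
    parse_category,
    validate_record,
)
from .threats import ThreatRecord, ThreatTiming

logger = logging.getLogger("rlikit")

__all__ = [
    "TableFormatError",
    "PipelineConfig",
    "read_assessments",
    "write_assessments",
    "read_ledger",
    "write_ledger",
    "read_threats",
    "write_threats",
    "read_incidence",
    "write_incidence",
    "attach_threats",
    "write_rli_series",
    "run_pipeline",
]

_BREEDING_COLUMNS = (
    "lays_eggs",
    "live_young",
    "parthenogenesis",
    "free_living_larva",
    "water_breeding",
)


class TableFormatError(ValueError):
    """One or more rows of an input table failed to parse."""

    def __init__(self, path, row_errors: list[str]):
        self.row_errors = row_errors
        super().__init__(
            f"{path}: {len(row_errors)} malformed row(s):\n  " + "\n  ".join(row_errors)
        )


def _tri(token: str) -> TriState:
    return TriState(str(token).strip().lower())


def read_assessments(
    path: Union[str, Path], epochs: Sequence[int] = DEFAULT_EPOCHS
) -> list[AssessmentRecord]:
    """Read an assessment table; raises :class:`TableFormatError` listing
    every malformed row with its line number."""
    df = pd.read_csv(path, dtype=str).fillna("")
    cat_cols = [f"cat_{e}" for e in epochs]
    missing = [c for c in ["species_id", "order", *cat_cols] if c not in df.columns]
    if missing:
        raise TableFormatError(path, [f"missing column(s): {', '.join(missing)}"])
    records: list[AssessmentRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            states = {e: parse_category(row[f"cat_{e}"]) for e in epochs}
            realms = frozenset(
                Realm(tok.strip())
                for tok in str(row.get("realms", "")).split(";")
                if tok.strip()
            )
            breeding = BreedingCodes(
                **{
                    col: _tri(row[col]) if col in df.columns and row[col] else TriState.UNKNOWN
                    for col in _BREEDING_COLUMNS
                }
            )
            records.append(
                AssessmentRecord(
                    species_id=str(row["species_id"]),
                    binomial=str(row.get("binomial", "")),
                    order=TaxonomicOrder(str(row["order"]).strip().capitalize()),
                    realms=realms,
                    states=states,
                    breeding=breeding,
                    unmapped=str(row.get("unmapped", "0")).strip() in ("1", "true", "True"),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise TableFormatError(path, errors)
    return records


def write_assessments(
    records: Iterable[AssessmentRecord],
    path: Union[str, Path],
    epochs: Sequence[int] = DEFAULT_EPOCHS,
) -> None:
    rows = []
    for r in records:
        row = {
            "species_id": r.species_id,
            "binomial": r.binomial,
            "order": r.order.value,
            "realms": ";".join(sorted(x.value for x in r.realms)),
        }
        for e in epochs:
            row[f"cat_{e}"] = format_category(r.state_at(e))
        for col in _BREEDING_COLUMNS:
            row[col] = getattr(r.breeding, col).value
        row["unmapped"] = int(r.unmapped)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ledger(path: Union[str, Path]) -> list[GenuineChangeDeclaration]:
    df = pd.read_csv(path, dtype=str).fillna("")
    decls = []
    errors = []
    for i, row in df.iterrows():
        try:
            decls.append(
                GenuineChangeDeclaration(
                    species_id=str(row["species_id"]),
                    interval=(int(row["epoch_from"]), int(row["epoch_to"])),
                    state_at_from=parse_category(row["state_at_from"]),
                    primary_driver=PrimaryDriver(str(row["primary_driver"]).strip().lower()),
                    n_codrivers=int(row.get("codriver_count", "1") or 1),
                    conservation_driven=str(row.get("conservation_driven", "0")).strip()
                    in ("1", "true", "True"),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2}: {exc}")
    if errors:
        raise TableFormatError(path, errors)
    return decls


def write_ledger(
    declarations: Iterable[GenuineChangeDeclaration], path: Union[str, Path]
) -> None:
    rows = [
        {
            "species_id": d.species_id,
            "epoch_from": d.interval[0],
            "epoch_to": d.interval[1],
            "state_at_from": format_category(d.state_at_from),
            "primary_driver": d.primary_driver.value,
            "codriver_count": d.n_codrivers,
            "conservation_driven": int(d.conservation_driven),
        }
        for d in declarations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "species_id", "epoch_from", "epoch_to", "state_at_from",
            "primary_driver", "codriver_count", "conservation_driven",
        ],
    ).to_csv(path, index=False)


def read_threats(path: Union[str, Path]) -> dict[str, list[ThreatRecord]]:
    """Read a threat table into a species_id -> threats mapping."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[str, list[ThreatRecord]] = {}
    errors = []
    for i, row in df.iterrows():
        try:
            major_tok = str(row.get("major", "")).strip()
            out.setdefault(str(row["species_id"]), []).append(
                ThreatRecord(
                    code=str(row["code"]).strip(),
                    timing=ThreatTiming(str(row["timing"]).strip().lower()),
                    named_agent=str(row.get("named_agent", "")).strip() or None,
                    major=None if not major_tok else major_tok in ("1", "true", "True"),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2}: {exc}")
    if errors:
        raise TableFormatError(path, errors)
    return out


def write_threats(
    threats: dict[str, list[ThreatRecord]], path: Union[str, Path]
) -> None:
    rows = [
        {
            "species_id": sid,
            "code": t.code,
            "timing": t.timing.value,
            "named_agent": t.named_agent or "",
            "major": "" if t.major is None else int(t.major),
        }
        for sid, ts in threats.items()
        for t in ts
    ]
    pd.DataFrame(
        rows, columns=["species_id", "code", "timing", "named_agent", "major"]
    ).to_csv(path, index=False)


def attach_threats(
    records: Iterable[AssessmentRecord], threats: dict[str, list[ThreatRecord]]
) -> list[AssessmentRecord]:
    return [
        dataclasses.replace(r, threats=tuple(threats.get(r.species_id, ())))
        for r in records
    ]


def read_incidence(
    path: Union[str, Path], grid: Optional[_spatial.GridSpec] = None
) -> _spatial.GridIncidence:
    df = pd.read_csv(path)
    pairs = [
        (str(row.species_id), (int(row.cell_col), int(row.cell_row)))
        for row in df.itertuples()
    ]
    return _spatial.incidence_from_pairs(pairs, grid)


def write_incidence(
    incidence: _spatial.GridIncidence, path: Union[str, Path]
) -> None:
    rows = [
        {"species_id": sid, "cell_col": cell[0], "cell_row": cell[1]}
        for cell, species in sorted(incidence.cells.items())
        for sid in sorted(species)
    ]
    pd.DataFrame(rows, columns=["species_id", "cell_col", "cell_row"]).to_csv(
        path, index=False
    )


def write_rli_series(
    series: Iterable[_rli.RLISeries], path: Union[str, Path]
) -> None:
    """group_label, epoch, rli, n_included, n_dd_excluded, slope_to_next."""
    rows = []
    for s in series:
        for i, epoch in enumerate(s.epochs):
            rows.append(
                {
                    "group_label": s.group_label,
                    "epoch": epoch,
                    "rli": s.values[i],
                    "n_included": s.n_included[i],
                    "n_dd_excluded": s.n_dd_excluded[i],
                    "slope_to_next": s.slopes[i] if i < len(s.slopes) else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults reproduce the published
    conventions (EW weighted 5, CR(PE)-to-EX excluded from deterioration
    tallies, EW not in the threatened set for threat tallies)."""

    assessments: Union[str, Path] = "assessments.csv"
    ledger: Optional[Union[str, Path]] = None
    threats: Optional[Union[str, Path]] = None
    incidence: Optional[Union[str, Path]] = None
    out_dir: Union[str, Path] = "out"
    epochs: tuple[int, ...] = DEFAULT_EPOCHS
    ew_weight: int = 5
    crpe_ex_as_none: bool = True
    include_ew_as_threatened: bool = False
    grid_preset: float = 7775.0
    rounding: int = 1
    log_level: str = "INFO"


def run_pipeline(config: PipelineConfig) -> dict:
    """Backcast -> changes -> RLI -> summaries -> (optional) threats/grid.

    Writes all output CSVs plus ``run_log.json`` recording the switch
    settings, and returns the in-memory report bundle.  Any stage failure
    propagates with a stage-tagged message.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def _stage(name: str):
        logger.info("stage: %s", name)

    try:
        _stage("read")
        records = read_assessments(config.assessments, config.epochs)
        declarations = read_ledger(config.ledger) if config.ledger else []
    except Exception as exc:
        raise RuntimeError(f"[read] {exc}") from exc

    try:
        _stage("validate")
        issues = {
            r.species_id: probs
            for r in records
            if (probs := validate_record(r, config.epochs))
        }
        report["validation_issues"] = issues
    except Exception as exc:
        raise RuntimeError(f"[validate] {exc}") from exc

    try:
        _stage("backcast")
        by_species: dict[str, list[GenuineChangeDeclaration]] = {}
        for d in declarations:
            by_species.setdefault(d.species_id, []).append(d)
        records = [
            r.with_states(
                _backcast.apply_backcast(r, by_species.get(r.species_id, []), config.epochs)
            )
            for r in records
        ]
        write_assessments(records, out_dir / "backcasted.csv", config.epochs)
    except Exception as exc:
        raise RuntimeError(f"[backcast] {exc}") from exc

    try:
        _stage("changes")
        changes = changes_for_records(
            records, declarations, config.epochs, crpe_ex_as_none=config.crpe_ex_as_none
        )
        table = tabulate_changes(changes)
        table.to_csv(out_dir / "changes.csv", index=False)
        report["changes"] = changes
        report["change_table"] = table
    except Exception as exc:
        raise RuntimeError(f"[changes] {exc}") from exc

    try:
        _stage("rli")
        all_series = []
        for grouping in ("global", "realm", "order", "breeding_strategy"):
            all_series.extend(
                _rli.rli_series(records, grouping, config.epochs, config.ew_weight)
            )
        write_rli_series(all_series, out_dir / "rli.csv")
        report["rli_series"] = all_series
    except Exception as exc:
        raise RuntimeError(f"[rli] {exc}") from exc

    try:
        _stage("summarize")
        counts = {e: _stats.count_categories(records, e) for e in config.epochs}
        fractions = {e: _stats.threatened_fraction(counts[e]) for e in config.epochs}
        accounting = _stats.extinction_accounting(records, config.epochs)
        intervals = list(zip(config.epochs[:-1], config.epochs[1:]))
        shares = {
            iv: _stats.driver_shares(changes, iv, ChangeDirection.DETERIORATION)
            for iv in intervals
        }
        report["category_counts"] = counts
        report["threatened_fractions"] = fractions
        report["extinction_accounting"] = accounting
        report["driver_shares"] = shares
        report["improvements"] = _stats.improvement_breakdown(changes)
        nd = config.rounding
        summary_rows = [
            {
                "epoch": e,
                "threatened_lower_pct": fractions[e].as_percent(nd)[0],
                "threatened_best_pct": fractions[e].as_percent(nd)[1],
                "threatened_upper_pct": fractions[e].as_percent(nd)[2],
                "dd_pct": _stats.round_half_away(
                    100 * _stats.dd_proportion(counts[e]), nd
                ),
                "cumulative_ex": accounting["cumulative_ex"][e],
                "cr_pe": accounting["cr_pe"][e],
            }
            for e in config.epochs
        ]
        pd.DataFrame(summary_rows).to_csv(out_dir / "summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[summarize] {exc}") from exc

    if config.threats:
        try:
            _stage("threats")
            threat_map = read_threats(config.threats)
            with_threats = attach_threats(records, threat_map)
            tally = _threats.tally_threats(
                with_threats,
                config.epochs[-1],
                include_ew=config.include_ew_as_threatened,
            )
            report["threat_tally"] = tally
            pd.DataFrame(
                [
                    {"group": g.value, **vals}
                    for g, vals in sorted(tally.counts.items(), key=lambda kv: kv[0].value)
                ]
            ).to_csv(out_dir / "threat_tally.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"[threats] {exc}") from exc

    if config.incidence:
        try:
            _stage("grid")
            grid = _spatial.GridSpec(cell_area=config.grid_preset)
            incidence = read_incidence(config.incidence, grid)
            classes = _spatial.richness_quantiles(incidence)
            richness = incidence.richness()
            last_interval = (config.epochs[-2], config.epochs[-1])
            drivers = _spatial.dominant_driver(
                incidence, report["changes"], last_interval
            )
            rows = []
            for cell in sorted(incidence.cells):
                lon, lat = grid.cell_centroid_lonlat(cell)
                d = drivers.get(cell)
                rows.append(
                    {
                        "cell_col": cell[0],
                        "cell_row": cell[1],
                        "centroid_lon": round(lon, 4),
                        "centroid_lat": round(lat, 4),
                        "richness": richness[cell],
                        "quantile_class": classes[cell],
                        "dominant_driver": "|".join(x.value for x in d.drivers) if d else "",
                        "tie_flag": int(d.tie_flag) if d else 0,
                        "star_flag": int(d.star_flag) if d else 0,
                    }
                )
            pd.DataFrame(rows).to_csv(out_dir / "grid.csv", index=False)
            report["grid_classes"] = classes
            report["grid_drivers"] = drivers
        except Exception as exc:
            raise RuntimeError(f"[grid] {exc}") from exc

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "epochs": list(config.epochs),
                "ew_weight": config.ew_weight,
                "crpe_ex_as_none": config.crpe_ex_as_none,
                "include_ew_as_threatened": config.include_ew_as_threatened,
                "grid_preset": config.grid_preset,
                "rounding": config.rounding,
                "n_records": len(records),
                "n_declarations": len(declarations),
            },
            fh,
            indent=2,
        )
    return report
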