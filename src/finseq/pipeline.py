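"""End-to-end analysis pipeline and report serialization.

Runs estimation (or loads the packaged published SL50 table in fixture
mode), then produces three JSON reports mirroring the published tables:
per-event SL50 profiles, direction-of-development calls, and the
dorsal/anal + endoskeleton/exoskeleton correlation table.  Fixture-
derived and estimated profiles flow through the same downstream code.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .coding import (EVENT_NAMES, EVENT_SERIES, SL50Profile,
                     load_published_sl50_table, read_coding_table,
                     smallest_specimen_sl)
from .modularity import (PUBLISHED_COLUMN_OFFSET, CorrelationResult, PairingMap,
                         dafpm_test, eem_test)
from .sequence import SequenceError, classify_direction
from .sl50 import SignificancePolicy, estimate_sl50_profile, fit_report

#: (event, label) rows of the dorsal/anal correlation table.
DAFPM_EVENTS = (2, 3, 4, 5, 6, 7, 8, 9, 10)

#: EEM rows: (endo event, exo event, label) tested within each fin.
EEM_ROWS = (
    (2, 4, "proximal_radial_and_lepidotrichium_apparition"),
    (5, 4, "distal_radial_and_lepidotrichium_apparition"),
    (10, 8, "proximal_radial_and_lepidotrichium_ossification"),
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    coding_path: str | None = None      # estimation mode input
    fixture_mode: bool = False          # use the packaged published table
    output_dir: str = "finseq_out"
    family_alpha: float = 0.05
    pairing_offset: int = PUBLISHED_COLUMN_OFFSET
    pairing_override: str | None = None  # CSV of position_a,position_b
    trend_threshold: float = 0.5
    min_flank: int = 1
    plateau_tol: float = 0.0
    include_always_present: bool = True
    seed: int = 0
    events: tuple = DAFPM_EVENTS

    def __post_init__(self):
        if not 0 < self.family_alpha < 1:
            raise ValueError("family_alpha must be in (0,1)")


def _round7(obj):
    """Serialize floats at 7 significant digits, recursively; numpy
    scalars become plain Python numbers."""
    import numpy as np
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.7g}")
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _round7(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round7(v) for v in obj]
    return obj


def load_profiles(config: PipelineConfig
                  ) -> dict[tuple[str, int], SL50Profile]:
    if config.fixture_mode:
        return {k: v for k, v in load_published_sl50_table().items()
                if k[1] in config.events}
    if not config.coding_path:
        raise PipelineError("input", "no coding table and not fixture mode")
    try:
        table = read_coding_table(config.coding_path)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    policy = SignificancePolicy(config.family_alpha)
    out = {}
    fins = sorted(table.frame.fin.unique())
    events = sorted(table.frame.event.unique())
    for fin in fins:
        for ev in events:
            if ev not in config.events:
                continue
            try:
                out[(fin, ev)] = estimate_sl50_profile(table, fin, ev,
                                                       policy)
            except Exception as exc:
                raise PipelineError(
                    "estimation", f"({fin}, event {ev}): {exc}") from exc
    return out


def proxy_size(fin: str, config: PipelineConfig) -> float | None:
    if not config.include_always_present:
        return None
    try:
        return smallest_specimen_sl(fin) if config.fixture_mode else None
    except KeyError:
        return None


def direction_table(profiles, config: PipelineConfig) -> list[dict]:
    rows = []
    for (fin, ev), prof in sorted(profiles.items(),
                                  key=lambda kv: (kv[0][1], kv[0][0])):
        try:
            call = classify_direction(prof, config.min_flank,
                                      config.trend_threshold,
                                      config.plateau_tol)
        except SequenceError:
            continue
        rows.append({
            "event": ev, "event_name": EVENT_NAMES[ev], "fin": fin,
            "direction": call.call,
            "initiation_site": list(call.initiation_site),
            "anterior_trend": call.anterior_trend,
            "posterior_trend": call.posterior_trend,
        })
    return rows


def _result_row(res: CorrelationResult, **extra) -> dict:
    row = {"n": res.n, "rho": res.rho, "p_value": res.p_value,
           "p_method": res.method, "significance": res.stars}
    row.update(extra)
    return row


def modularity_table(profiles, config: PipelineConfig) -> dict:
    override = None
    if config.pairing_override:
        import pandas as pd
        f = pd.read_csv(config.pairing_override)
        override = PairingMap(
            tuple(zip(f.position_a.astype(int), f.position_b.astype(int))),
            "published_columns")
    dafpm, eem = [], []
    for ev in DAFPM_EVENTS:
        d = profiles.get(("dorsal", ev))
        a = profiles.get(("anal", ev))
        if d is None or a is None:
            continue
        use_proxy = ev == 2  # radial apparition: smallest specimens count
        try:
            res = dafpm_test(
                d, a,
                dorsal_proxy_size=proxy_size("dorsal", config)
                if use_proxy else None,
                anal_proxy_size=proxy_size("anal", config)
                if use_proxy else None)
        except Exception:
            continue
        dafpm.append(_result_row(res, event=ev,
                                 event_name=EVENT_NAMES[ev]))
    for endo_ev, exo_ev, label in EEM_ROWS:
        for fin in ("dorsal", "anal"):
            endo = profiles.get((fin, endo_ev))
            exo = profiles.get((fin, exo_ev))
            if endo is None or exo is None:
                continue
            pairing = override or PairingMap.column_aligned(
                endo, exo, config.pairing_offset)
            use_proxy = endo_ev == 2
            try:
                res = eem_test(
                    endo, exo, pairing,
                    endo_proxy_size=proxy_size(fin, config)
                    if use_proxy else None)
            except Exception:
                continue
            eem.append(_result_row(res, fin=fin, events=[endo_ev, exo_ev],
                                   label=label))
    return {"dafpm": dafpm, "eem": eem}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write the report bundle; returns output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = load_profiles(config)

    try:
        sl50_doc = [{
            "fin": fin, "event": ev, "event_name": EVENT_NAMES[ev],
            "series": EVENT_SERIES.get(ev),
            "n_elements_tested": prof.n_elements_tested,
            "entries": fit_report(prof),
        } for (fin, ev), prof in sorted(profiles.items(),
                                        key=lambda kv: (kv[0][1], kv[0][0]))]
        directions = direction_table(profiles, config)
        modularity = modularity_table(profiles, config)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - stage guard
        raise PipelineError("analysis", str(exc)) from exc

    log = {
        "finseq_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
    }
    paths = {}
    for name, doc in (("sl50_profiles", sl50_doc),
                      ("directions", directions),
                      ("modularity", modularity),
                      ("run_log", log)):
        p = out / f"{name}.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(_round7(doc), fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths[name] = p
    return paths


def reproduce_correlations() -> list[dict]:
    """Recompute every row of the published correlation table from the
    packaged SL50 fixture and report the comparison."""
    from .data.published_correlations import PUBLISHED_CORRELATIONS
    profiles = load_published_sl50_table()
    cfg = PipelineConfig(fixture_mode=True)
    got = modularity_table(profiles, cfg)
    rows = []
    for kind in ("dafpm", "eem"):
        for res in got[kind]:
            if kind == "dafpm":
                key = ("dafpm", res["event"], None)
            else:
                key = ("eem", tuple(res["events"]), res["fin"])
            exp = PUBLISHED_CORRELATIONS.get(key)
            if exp is None:
                continue
            if exp.get("exact", True):
                ok = (res["n"] == exp["n"]
                      and abs(res["rho"] - exp["rho"]) <= 0.005)
                check = "exact"
            else:  # under-determined row: sign and rough magnitude only
                ok = (res["rho"] * exp["rho"] > 0
                      and abs(res["rho"] - exp["rho"]) <= 0.2)
                check = "qualitative"
            rows.append({
                "module": kind.upper(),
                "row": exp["label"],
                "check": check,
                "n": res["n"], "expected_n": exp["n"],
                "rho": res["rho"], "expected_rho": exp["rho"],
                "pass": bool(ok),
            })
    return rows
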