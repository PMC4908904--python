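"""Tabular readers/writers for parameter sets and risk profiles.

A parameter set lives in a directory of plain comma-separated files bound
together by a ``manifest.yaml``: one file per equation (columns
``term,estimate``; spline coefficients appear as terms ``spline.0``,
``spline.1``, ... with the knot vector recorded in the manifest), a utility
table, a decrement table, cost-curve files and a variance-covariance matrix
with a header row/column of parameter names.  Values are written at full
repr precision so a write/read round trip is bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import LoadError, ValidationError
from .parameters import (
    FIRST_EVENTS,
    POST_DEATH_EQS,
    POST_STATES,
    SUBSEQUENT_EVENTS,
    CostCurve,
    CostModel,
    DecrementSet,
    EventEquation,
    ParameterSet,
    UtilityTable,
)
from .profiles import RiskProfile

MANIFEST = "manifest.yaml"
_PROFILE_COLUMNS = [
    "age",
    "sex",
    "simd",
    "family_history",
    "diabetes",
    "sbp",
    "total_chol",
    "hdl_chol",
    "cigarettes_per_day",
]


def _equation_frame(eq: EventEquation) -> pd.DataFrame:
    rows = [("intercept", eq.intercept)]
    rows += list(eq.betas.items())
    if eq.spline_coefs is not None:
        rows += [(f"spline.{i}", c) for i, c in enumerate(eq.spline_coefs)]
    return pd.DataFrame(rows, columns=["term", "estimate"])


def _equation_from_frame(frame: pd.DataFrame, knots, name: str) -> EventEquation:
    terms = dict(zip(frame["term"], frame["estimate"]))
    if "intercept" not in terms:
        raise LoadError(f"equation {name!r} has no intercept row")
    intercept = terms.pop("intercept")
    spline = {k: v for k, v in terms.items() if k.startswith("spline.")}
    betas = {k: v for k, v in terms.items() if not k.startswith("spline.")}
    coefs = None
    if spline:
        coefs = tuple(spline[f"spline.{i}"] for i in range(len(spline)))
        if knots is None:
            raise LoadError(f"equation {name!r} has spline terms but no knots in manifest")
    return EventEquation(
        intercept=intercept,
        betas=betas,
        spline_knots=tuple(knots) if coefs is not None else None,
        spline_coefs=coefs,
    )


def _cost_curve_entry(curve: CostCurve, path: Path, fname: str) -> dict:
    rows = [("intercept", curve.intercept)]
    if curve.u_coefs is not None:
        rows += [(f"u.{i}", c) for i, c in enumerate(curve.u_coefs)]
    if curve.age_coefs is not None:
        rows += [(f"age.{i}", c) for i, c in enumerate(curve.age_coefs)]
    pd.DataFrame(rows, columns=["term", "estimate"]).to_csv(path / fname, index=False, float_format="%.17g")
    entry = {"file": fname}
    if curve.u_knots is not None:
        entry["u_knots"] = [float(k) for k in curve.u_knots]
    if curve.age_knots is not None:
        entry["age_knots"] = [float(k) for k in curve.age_knots]
    return entry


def _cost_curve_from_entry(entry: dict, path: Path, name: str) -> CostCurve:
    frame = _read_table(path / entry["file"], name)
    terms = dict(zip(frame["term"], frame["estimate"]))
    intercept = terms.pop("intercept", 0.0)
    u = [terms[f"u.{i}"] for i in range(sum(k.startswith("u.") for k in terms))]
    age = [terms[f"age.{i}"] for i in range(sum(k.startswith("age.") for k in terms))]
    return CostCurve(
        intercept=intercept,
        u_knots=tuple(entry["u_knots"]) if u else None,
        u_coefs=tuple(u) if u else None,
        age_knots=tuple(entry["age_knots"]) if age else None,
        age_coefs=tuple(age) if age else None,
    )


def _read_table(path: Path, what: str) -> pd.DataFrame:
    if not path.exists():
        raise LoadError(f"missing file for {what}: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def write_parameter_set(params: ParameterSet, directory) -> None:
    """Write a parameter set as a directory of tabular files + manifest."""
    path = Path(directory)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sex": params.sex,
        "label": params.label,
        "metadata": dict(params.metadata),
        "event_equations": {},
        "subsequent_event_equations": {},
        "cost_model": {"terminal_cost": float(params.cost_model.terminal_cost)},
    }
    for name, eq in params.event_models.items():
        fname = f"event_{name}.csv"
        _equation_frame(eq).to_csv(path / fname, index=False, float_format="%.17g")
        entry = {"file": fname}
        if eq.spline_knots is not None:
            entry["knots"] = [float(k) for k in eq.spline_knots]
        manifest["event_equations"][name] = entry
    for state, eqs in params.subsequent_event_models.items():
        manifest["subsequent_event_equations"][state] = {}
        for ev, eq in eqs.items():
            fname = f"subseq_{state}_{ev}.csv"
            _equation_frame(eq).to_csv(path / fname, index=False, float_format="%.17g")
            entry = {"file": fname}
            if eq.spline_knots is not None:
                entry["knots"] = [float(k) for k in eq.spline_knots]
            manifest["subsequent_event_equations"][state][ev] = entry

    params.utility_table.to_frame().to_csv(path / "utility_table.csv", index=False, float_format="%.17g")
    manifest["utility_table"] = {"file": "utility_table.csv"}
    pd.DataFrame(
        [(e, params.decrements.values[e]) for e in SUBSEQUENT_EVENTS],
        columns=["event", "delta"],
    ).to_csv(path / "decrements.csv", index=False, float_format="%.17g")
    manifest["decrements"] = {"file": "decrements.csv"}

    manifest["cost_model"]["pre_event"] = _cost_curve_entry(
        params.cost_model.pre_event, path, "cost_pre_event.csv"
    )
    manifest["cost_model"]["post_event"] = {
        ev: _cost_curve_entry(curve, path, f"cost_post_{ev}.csv")
        for ev, curve in params.cost_model.post_event.items()
    }

    if params.vcov is not None:
        names = list(params.param_names)
        pd.DataFrame(params.vcov, index=names, columns=names).to_csv(path / "vcov.csv", float_format="%.17g")
        manifest["vcov"] = {"file": "vcov.csv"}

    with open(path / MANIFEST, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_parameter_set(directory) -> ParameterSet:
    """Load a parameter set directory; validates PSD-ness and term coverage."""
    path = Path(directory)
    mpath = path / MANIFEST
    if not mpath.exists():
        raise LoadError(f"no {MANIFEST} in {path}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)

    events = {}
    required = set(FIRST_EVENTS) | set(POST_DEATH_EQS.values())
    declared = manifest.get("event_equations", {})
    missing = required - set(declared)
    if missing:
        raise LoadError(f"manifest missing event equations: {sorted(missing)}")
    for name, entry in declared.items():
        frame = _read_table(path / entry["file"], f"event equation {name!r}")
        events[name] = _equation_from_frame(frame, entry.get("knots"), name)

    subseq = {}
    for state in POST_STATES:
        entries = manifest.get("subsequent_event_equations", {}).get(state, {})
        missing = set(SUBSEQUENT_EVENTS) - set(entries)
        if missing:
            raise LoadError(
                f"manifest missing subsequent-event equations for {state}: "
                f"{sorted(missing)}"
            )
        subseq[state] = {
            ev: _equation_from_frame(
                _read_table(path / entry["file"], f"subsequent equation {state}/{ev}"),
                entry.get("knots"),
                f"{state}/{ev}",
            )
            for ev, entry in entries.items()
        }

    table = UtilityTable.from_frame(
        _read_table(path / manifest["utility_table"]["file"], "utility table")
    )
    dec_frame = _read_table(path / manifest["decrements"]["file"], "decrements")
    decrements = DecrementSet(dict(zip(dec_frame["event"], dec_frame["delta"])))

    cm_entry = manifest["cost_model"]
    pre = _cost_curve_from_entry(cm_entry["pre_event"], path, "pre-event cost curve")
    post = {
        ev: _cost_curve_from_entry(entry, path, f"post-event cost curve {ev}")
        for ev, entry in cm_entry["post_event"].items()
    }
    cost_model = CostModel(
        pre_event=pre, post_event=post, terminal_cost=cm_entry.get("terminal_cost", 0.0)
    )

    vcov = None
    names = None
    if "vcov" in manifest:
        vframe = pd.read_csv(
            path / manifest["vcov"]["file"], index_col=0, float_precision="round_trip"
        )
        vcov = vframe.to_numpy(dtype=float)
        names = tuple(vframe.columns)

    params = ParameterSet(
        sex=manifest["sex"],
        event_models=events,
        subsequent_event_models=subseq,
        utility_table=table,
        decrements=decrements,
        cost_model=cost_model,
        vcov=vcov,
        param_names=names,
        label=manifest.get("label", ""),
        metadata=manifest.get("metadata") or {},
    )
    violations = params.validate()
    if violations:
        raise ValidationError(
            f"parameter set in {path} failed validation: " + "; ".join(violations)
        )
    return params


def write_profiles(profiles, path) -> None:
    """Write risk profiles as a tabular file, one row per individual."""
    rows = [
        {c: getattr(p, c) for c in _PROFILE_COLUMNS}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> list[RiskProfile]:
    """Read risk profiles from a tabular file with RiskProfile-named columns."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(_PROFILE_COLUMNS) - set(frame.columns)
    if missing:
        raise LoadError(f"profile file {path} missing columns: {sorted(missing)}")
    return [
        RiskProfile(**{c: row[c] for c in _PROFILE_COLUMNS})
        for _, row in frame.iterrows()
    ]
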