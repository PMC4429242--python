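"""CSV/JSON serialisation of records, protocols, cohort summaries and fits.

All floats are written with 17 significant digits so write/read round-trips
are lossless to double precision.  Column conventions:

* input traces:  ``time_s, sao2, pa_mmHg, paco2_mmHg, occ``
* observables:   ``time_s, dHbO2_mM, dHHb_mM, doxCCO_mM, pH, cmro2_pct,
  cbf_pct, ntp_frac``
* piglet records: ``time_s, sao2, pa_mmHg, dHbO2_mM, dHHb_mM, doxCCO_mM, pH``
* phase boundaries: ``piglet_id, phase, start_s, end_s``
* group averages (long): ``signal, phase, section, mean, sd, n``
"""

from __future__ import annotations

import json
import pathlib
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fit import OptimisationResult
from .group import (
    N_PHASES,
    GroupAverage,
    PhaseBoundaries,
    PigletRecord,
)
from .model import InputTrace, SimulationResult
from .parameters import save_parameters

__all__ = [
    "read_inputs",
    "write_inputs",
    "write_observables",
    "read_record",
    "write_record",
    "read_records",
    "write_cohort",
    "read_boundaries",
    "write_boundaries",
    "write_group_average",
    "read_group_average",
    "write_optimisation_result",
    "read_optimisation_result",
]

_FLOAT_FMT = "%.17g"

# record signal name <-> CSV column
_RECORD_COLS = {
    "sao2": "sao2",
    "pa": "pa_mmHg",
    "dHbO2": "dHbO2_mM",
    "dHHb": "dHHb_mM",
    "doxCCO": "doxCCO_mM",
    "pH": "pH",
}


def _read_numeric_csv(path, required: Iterable[str]) -> pd.DataFrame:
    """Read a CSV of floats, reporting offending columns and rows."""
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
        if bad.any():
            # +2: header line and 1-based numbering
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
            raise ValueError(
                f"{path.name}: non-numeric values in column {col!r} "
                f"at lines {lines[:10]}"
            )
        df[col] = coerced
    return df


# --------------------------------------------------------------------- inputs


def write_inputs(u: InputTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": u.t,
            "sao2": u.sao2,
            "pa_mmHg": u.pa,
            "paco2_mmHg": u.paco2,
            "occ": u.occ,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_inputs(path) -> InputTrace:
    df = _read_numeric_csv(path, ["time_s", "sao2", "pa_mmHg", "occ"])
    paco2 = (
        df["paco2_mmHg"].to_numpy()
        if "paco2_mmHg" in df.columns
        else np.full(len(df), 40.0)  # assumed constant normocapnia when absent
    )
    return InputTrace(
        df["time_s"].to_numpy(),
        df["sao2"].to_numpy(),
        df["pa_mmHg"].to_numpy(),
        paco2,
        df["occ"].to_numpy(),
    )


def write_observables(res: SimulationResult, path, units: str = "mM") -> None:
    """Write simulated observables; ``units='uM'`` rescales the
    concentration-change columns for display."""
    if units not in ("mM", "uM"):
        raise ValueError("units must be 'mM' or 'uM'")
    scale = 1.0 if units == "mM" else 1e3
    o = res.observables
    df = pd.DataFrame(
        {
            "time_s": res.t,
            f"dHbO2_{units}": scale * o["dHbO2_mM"],
            f"dHHb_{units}": scale * o["dHHb_mM"],
            f"doxCCO_{units}": scale * o["doxCCO_mM"],
            "pH": o["pH"],
            "cmro2_pct": o["cmro2_pct"],
            "cbf_pct": o["cbf_pct"],
            "ntp_frac": o["ntp_frac"],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -------------------------------------------------------------------- records


def write_record(rec: PigletRecord, path) -> None:
    data = {"time_s": rec.t}
    for name, col in _RECORD_COLS.items():
        if name in rec.signals:
            data[col] = rec.signals[name]
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_record(path, piglet_id: str | None = None) -> PigletRecord:
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    missing = [
        name
        for name, col in _RECORD_COLS.items()
        if col not in df.columns
    ]
    if missing:
        raise ValueError(f"{path.name}: missing signal columns {missing}")
    df = _read_numeric_csv(path, ["time_s"])
    signals = {
        name: df[col].to_numpy() for name, col in _RECORD_COLS.items()
    }
    return PigletRecord(
        piglet_id=piglet_id or path.stem, t=df["time_s"].to_numpy(), signals=signals
    )


def read_records(directory) -> list[PigletRecord]:
    """Read every ``*.csv`` piglet record in a directory (sorted by name,
    skipping the boundaries file)."""
    directory = pathlib.Path(directory)
    recs = []
    for f in sorted(directory.glob("*.csv")):
        if f.stem in ("boundaries", "group_average"):
            continue
        recs.append(read_record(f))
    if not recs:
        raise FileNotFoundError(f"no piglet record CSVs in {directory}")
    return recs


# ----------------------------------------------------------------- boundaries


def write_boundaries(
    bounds: Mapping[str, PhaseBoundaries] | list[PhaseBoundaries],
    path,
    piglet_ids: list[str] | None = None,
) -> None:
    if not isinstance(bounds, Mapping):
        ids = piglet_ids or [f"piglet{i:02d}" for i in range(len(bounds))]
        bounds = dict(zip(ids, bounds))
    rows = []
    for pid, pb in bounds.items():
        for i in range(N_PHASES):
            lo, hi = pb.window(i)
            rows.append(
                {"piglet_id": pid, "phase": i + 1, "start_s": lo, "end_s": hi}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_boundaries(path) -> dict[str, PhaseBoundaries]:
    df = pd.read_csv(path)
    need = ["piglet_id", "phase", "start_s", "end_s"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"boundaries file missing columns {missing}")
    out = {}
    for pid, grp in df.groupby("piglet_id", sort=False):
        grp = grp.sort_values("phase")
        if list(grp["phase"]) != list(range(1, N_PHASES + 1)):
            raise ValueError(f"piglet {pid!r}: expected phases 1..{N_PHASES}")
        edges = np.concatenate(
            [grp["start_s"].to_numpy(), [grp["end_s"].to_numpy()[-1]]]
        )
        out[str(pid)] = PhaseBoundaries(edges)
    return out


def write_cohort(cohort, directory) -> list[pathlib.Path]:
    """Write a synthetic cohort: one record CSV per piglet, a boundaries
    CSV, and the ground-truth parameter file ``truth.json``."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in cohort.records:
        f = directory / f"{rec.piglet_id}.csv"
        write_record(rec, f)
        written.append(f)
    bfile = directory / "boundaries.csv"
    write_boundaries(
        dict(zip([r.piglet_id for r in cohort.records], cohort.boundaries)), bfile
    )
    written.append(bfile)
    tfile = directory / "truth.json"
    save_parameters(cohort.truth, tfile)
    written.append(tfile)
    return written


# -------------------------------------------------------------- group average


def write_group_average(ga: GroupAverage, prefix) -> tuple[pathlib.Path, pathlib.Path]:
    """Write a GroupAverage as a long CSV plus a JSON with durations."""
    prefix = pathlib.Path(prefix)
    rows = []
    for sig in sorted(ga.mean):
        m, s, n = ga.mean[sig], ga.sd[sig], ga.n[sig]
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                rows.append(
                    {
                        "signal": sig,
                        "phase": i + 1,
                        "section": j + 1,
                        "mean": m[i, j],
                        "sd": s[i, j],
                        "n": int(n[i, j]),
                    }
                )
    csv_path = prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    json_path = prefix.with_suffix(".json")
    payload = {
        "durations_s": [float(d) for d in ga.durations],
        "piglet_ids": ga.piglet_ids,
        "n_sections": ga.n_sections,
        "signals": sorted(ga.mean),
    }
    json_path.write_text(json.dumps(payload, indent=1) + "\n")
    return csv_path, json_path


def read_group_average(prefix) -> GroupAverage:
    prefix = pathlib.Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    S = int(meta["n_sections"])
    mean, sd, n = {}, {}, {}
    for sig, grp in df.groupby("signal"):
        m = np.full((N_PHASES, S), np.nan)
        s_ = np.full((N_PHASES, S), np.nan)
        cnt = np.zeros((N_PHASES, S))
        for _, row in grp.iterrows():
            i, j = int(row["phase"]) - 1, int(row["section"]) - 1
            m[i, j], s_[i, j], cnt[i, j] = row["mean"], row["sd"], row["n"]
        mean[sig], sd[sig], n[sig] = m, s_, cnt
    return GroupAverage(
        mean=mean,
        sd=sd,
        n=n,
        durations=np.array(meta["durations_s"], dtype=float),
        per_piglet={},
        piglet_ids=list(meta["piglet_ids"]),
    )


# ----------------------------------------------------------------------- fits


def write_optimisation_result(res: OptimisationResult, path) -> None:
    payload = {
        "param_names": list(res.param_names),
        "values": [float(v) for v in res.values],
        "cost": res.cost,
        "cost_trace": [float(c) for c in res.cost_trace],
        "n_evaluations": res.n_evaluations,
        "seed": res.seed,
        "converged": res.converged,
        "message": res.message,
    }
    pathlib.Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_optimisation_result(path) -> OptimisationResult:
    d = json.loads(pathlib.Path(path).read_text())
    return OptimisationResult(
        param_names=tuple(d["param_names"]),
        values=np.array(d["values"], dtype=float),
        cost=float(d["cost"]),
        cost_trace=np.array(d["cost_trace"], dtype=float),
        n_evaluations=int(d["n_evaluations"]),
        seed=int(d["seed"]),
        converged=bool(d["converged"]),
        message=str(d["message"]),
    )
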