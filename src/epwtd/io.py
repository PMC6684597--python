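"""File formats: networks and models (YAML), trajectories and densities (TSV).

Conventions: tab-separated values with '.' decimals and '#'-prefixed
metadata comments; numeric output carries 12 significant digits; rate
matrices are stored dense, row = destination, column = source (the
``omega[i, j]`` = rate j -> i orientation used throughout).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coarse_grain import PairTrajectory, Partition
from .gillespie import Trajectory
from .markov import ObservedLink, RateNetwork, four_state_network, random_network
from .motor import MotorSpec, build_motor_network
from .semimarkov import DensityOnGrid, EPReport, SemiMarkovModel

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# rate networks
# ---------------------------------------------------------------------------

def write_network(net: RateNetwork, path, link: ObservedLink | None = None,
                  comment: str | None = None) -> None:
    doc = {
        "states": list(net.states),
        "beta": float(net.beta),
        "L": float(net.L),
        # row = destination state, column = source state
        "omega": [[float(x) for x in row] for row in net.omega],
    }
    if link is not None:
        doc["observed_link"] = [link.state_1, link.state_2]
    if comment:
        doc["comment"] = comment
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_network(path) -> tuple[RateNetwork, ObservedLink | None]:
    doc = yaml.safe_load(Path(path).read_text())
    net = RateNetwork(states=tuple(doc["states"]),
                      omega=np.asarray(doc["omega"], dtype=float),
                      beta=float(doc.get("beta", 1.0)),
                      L=float(doc.get("L", 1.0)))
    link = None
    if "observed_link" in doc:
        link = ObservedLink(*doc["observed_link"])
    return net, link


def make_fixture(kind: str, seed: int = 0) -> tuple[RateNetwork, ObservedLink | None]:
    """Bundled example networks: the four-state hidden network (``fig3``),
    the molecular motor ring (``motor``), or a seeded ``random`` 4-state net."""
    if kind == "fig3":
        return four_state_network(), ObservedLink("1", "2")
    if kind == "motor":
        return build_motor_network(MotorSpec()), None
    if kind == "random":
        return random_network(seed), None
    raise ValueError(f"unknown fixture kind {kind!r}; use fig3, motor or random")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for k, v in traj.origin.items():
            fh.write(f"# {k}: {json.dumps(v)}\n")
        fh.write("state\tdwell_s\n")
        for s, d in zip(traj.states, traj.dwells):
            fh.write(f"{s}\t{_FLOAT_FMT % d}\n")


def read_trajectory(path) -> Trajectory:
    origin = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            try:
                origin[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                origin[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"state": str})
    _require_columns(df, ("state", "dwell_s"), path)
    return Trajectory(states=df["state"].tolist(),
                      dwells=df["dwell_s"].to_numpy(), origin=origin)


def write_pair_trajectory(ptraj: PairTrajectory, path) -> None:
    with open(path, "w") as fh:
        for k, v in ptraj.origin.items():
            fh.write(f"# {k}: {json.dumps(v)}\n")
        fh.write("prev\tcurr\tdwell_s\n")
        for (a, b), d in zip(ptraj.pairs, ptraj.dwells):
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT % d}\n")


def read_pair_trajectory(path) -> PairTrajectory:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"prev": str, "curr": str})
    _require_columns(df, ("prev", "curr", "dwell_s"), path)
    pairs = list(zip(df["prev"], df["curr"]))
    return PairTrajectory(pairs=pairs, dwells=df["dwell_s"].to_numpy())


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in cols:
        bad = df[df[c].isna()]
        if len(bad):
            raise ValueError(f"{path}: unparsable value in column {c!r} at "
                             f"data line {int(bad.index[0]) + 2}")


# ---------------------------------------------------------------------------
# densities, models and reports
# ---------------------------------------------------------------------------

def write_density(dens: DensityOnGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("t_s\tdensity_per_s\n")
        for t, f in zip(dens.t, dens.f):
            fh.write(f"{_FLOAT_FMT % t}\t{_FLOAT_FMT % f}\n")


def read_density(path) -> DensityOnGrid:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("t_s", "density_per_s"), path)
    return DensityOnGrid(df["t_s"].to_numpy(), df["density_per_s"].to_numpy())


def write_model(model: SemiMarkovModel, path, density_dir=None) -> None:
    """Serialize a semi-Markov model: YAML document plus per-edge WTD spec.

    Densities are written as tabulated two-column TSV files next to the
    model document (or in ``density_dir``).
    """
    path = Path(path)
    ddir = Path(density_dir) if density_dir else path.parent
    ddir.mkdir(parents=True, exist_ok=True)
    doc = {
        "order": model.order,
        "states": [list(s) if isinstance(s, tuple) else s for s in model.states],
        "p": [[float(x) for x in row] for row in model.p],
        "tau": [float(t) for t in model.tau],
        "reversal": {_skey(s): _skey(model.reversal[s]) for s in model.states},
        "wtd": {},
    }
    for n, ((sa, sb), dens) in enumerate(model.wtd.items()):
        fname = f"{path.stem}_wtd_{n:03d}.tsv"
        write_density(dens, ddir / fname)
        doc["wtd"][f"{_skey(sa)} -> {_skey(sb)}"] = {"kind": "grid", "file": fname}
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model(path) -> SemiMarkovModel:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    states = [tuple(s) if isinstance(s, list) else s for s in doc["states"]]
    bykey = {_skey(s): s for s in states}
    wtd = {}
    for edge, spec in doc["wtd"].items():
        a, _, b = edge.partition(" -> ")
        if spec["kind"] == "grid":
            dens = read_density(path.parent / spec["file"])
        elif spec["kind"] == "exponential":
            from .semimarkov import exponential_density
            dens = exponential_density(float(spec["rate"]))
        else:
            raise ValueError(f"unknown wtd kind {spec['kind']!r}")
        wtd[(bykey[a], bykey[b])] = dens
    reversal = {bykey[a]: bykey[b] for a, b in doc["reversal"].items()}
    return SemiMarkovModel(states=states, p=np.asarray(doc["p"], dtype=float),
                           wtd=wtd, order=int(doc["order"]), reversal=reversal,
                           tau=np.asarray(doc["tau"], dtype=float))


def _skey(s) -> str:
    return "|".join(s) if isinstance(s, tuple) else str(s)


def report_to_dict(report: EPReport) -> dict:
    return {
        "S_aff_per_s": report.S_aff,
        "S_wtd_per_s": report.S_wtd,
        "S_kld_per_s": report.S_kld,
        "mean_step_time_s": report.T_step,
        "visit_distribution": {_skey(k): v for k, v in report.R.items()},
        "current_per_step": {f"{_skey(a)} -> {_skey(b)}": v
                             for (a, b), v in report.J_per_step.items()},
        "wtd_terms_per_s": {f"{_skey(a)} -> {_skey(b)}": v
                            for (a, b), v in report.wtd_terms.items()},
        "aff_terms_per_s": {f"{_skey(a)} -> {_skey(b)}": v
                            for (a, b), v in report.aff_terms.items()},
        "warnings": list(report.warnings),
    }


def write_report(report: EPReport, path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2,
                                     default=float) + "\n")


def read_partition(observed, hidden, hidden_label="H") -> Partition:
    return Partition(observed=tuple(observed), hidden=tuple(hidden),
                     hidden_label=hidden_label)
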