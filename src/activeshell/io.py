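"""Plain-text state serialisation: one TSV table plus a JSON metadata file.

A state written to ``base`` produces ``base.tsv`` (per-arclength columns)
and ``base.json`` (parameters, pattern, time, pressure, volume).  Floats are
written with 17 significant digits so a round trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .activity import ActivityPattern, evaluate_profiles
from .dynamics import ShellState
from .geometry import AxisymShape, MaterialMap
from .mechanics import (
    Parameters,
    constitutive_moments,
    constitutive_tensions,
    flow_kinematics,
)
from .nematic import NematicField

__all__ = ["write_state", "read_state", "SchemaError"]

COLUMNS = [
    "s", "x", "z", "psi", "Css", "Cphiphi", "q", "u", "s0",
    "zeta", "zeta_n", "zeta_c", "zeta_cn",
    "tss", "tphiphi", "tns", "mss", "mphiphi", "vs", "vn",
]


class SchemaError(ValueError):
    pass


def write_state(state: ShellState, base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    sh = state.shape
    prof = evaluate_profiles(state.pattern, state.mmap.s0, t=state.t)
    q = state.q
    flow = state.flow
    tss, tphiphi = constitutive_tensions(sh, flow, state.mmap.u, q, prof, state.params)
    mss, mphiphi, tns = constitutive_moments(sh, flow, q, prof, state.params)
    vs = flow.vs if flow is not None else np.zeros_like(sh.s)
    vn = flow.vn if flow is not None else np.zeros_like(sh.s)
    table = pd.DataFrame({
        "s": sh.s, "x": sh.x, "z": sh.z, "psi": sh.psi,
        "Css": sh.css, "Cphiphi": sh.cphiphi, "q": q,
        "u": state.mmap.u, "s0": state.mmap.s0,
        "zeta": prof["zeta"], "zeta_n": prof["zeta_n"],
        "zeta_c": prof["zeta_c"], "zeta_cn": prof["zeta_cn"],
        "tss": tss, "tphiphi": tphiphi, "tns": tns,
        "mss": mss, "mphiphi": mphiphi, "vs": vs, "vn": vn,
    })
    tsv = base.with_suffix(".tsv")
    meta = base.with_suffix(".json")
    table.to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    payload = {
        "format": "activeshell-state-v1",
        "t": state.t,
        "P": state.P,
        "V": state.V,
        "L": sh.L,
        "volume_mode": state.volume_mode,
        "params": dataclasses.asdict(state.params),
        "pattern": dataclasses.asdict(state.pattern),
        "has_nematic": state.nematic is not None,
        "lc": state.params.lc,
    }
    meta.write_text(json.dumps(payload, indent=1))
    return tsv, meta


def read_state(base: str | Path) -> ShellState:
    base = Path(base)
    tsv, meta = base.with_suffix(".tsv"), base.with_suffix(".json")
    try:
        payload = json.loads(meta.read_text())
        if payload.get("format") != "activeshell-state-v1":
            raise SchemaError(f"unrecognised state format in {meta}")
        table = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
    except (json.JSONDecodeError, FileNotFoundError) as err:
        raise SchemaError(f"cannot read state at {base}: {err}") from err
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"state table missing columns: {missing}")

    shape = AxisymShape(
        s=table["s"].to_numpy(), x=table["x"].to_numpy(), z=table["z"].to_numpy(),
        psi=table["psi"].to_numpy(), css=table["Css"].to_numpy(),
        cphiphi=table["Cphiphi"].to_numpy(), L=float(payload["L"]),
    )
    s0 = table["s0"].to_numpy()
    u = table["u"].to_numpy()
    ds0 = CubicSpline(shape.s, s0).derivative()(shape.s)
    fs = 1.0 / np.clip(ds0, 1e-12, None)
    fphi = (1.0 + u) / fs
    mmap = MaterialMap(s0=s0, u=u, fs=fs, fphi=fphi)
    params = Parameters(**payload["params"])
    pattern = ActivityPattern(**payload["pattern"])
    nem = None
    if payload.get("has_nematic"):
        qcol = table["q"].to_numpy()
        nem = NematicField(q=qcol, dq=CubicSpline(shape.s, qcol).derivative()(shape.s),
                          lc=float(payload["lc"]),
                          trivial=bool(np.max(np.abs(qcol)) < 1e-3))
    return ShellState(
        t=float(payload["t"]), shape=shape, mmap=mmap, pattern=pattern,
        params=params, volume_mode=payload["volume_mode"], nematic=nem,
        P=float(payload["P"]), V=float(payload["V"]),
    )
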