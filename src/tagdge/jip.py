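"""JIP-test analysis of fast chlorophyll-a fluorescence (OJIP) transients.

A dark-adapted leaf exposed to saturating light shows a polyphasic
fluorescence rise with inflections O (origin), J (~2 ms), I (~30 ms) and
P (peak, Fm).  The JIP-test reads five marks off the transient —

    Fo at 50 us, Fk at 300 us, Fj at 2 ms (J), Fi at 30 ms (I),
    Fm = the maximum —

and derives photosystem II energy-flux parameters:

    Vj     = (Fj - Fo) / (Fm - Fo)   relative variable fluorescence at J
    Mo     = 4 (Fk - Fo) / (Fm - Fo) initial slope of V kinetics (per ms)
    Wk     = (Fk - Fo) / (Fj - Fo)   donor-side (OEC damage) indicator
    phi_Po = 1 - Fo/Fm               max quantum yield of primary
                                     photochemistry (= Fv/Fm)
    phi_Eo = (Fm - Fj) / Fm          quantum yield of electron transport
    psi_Eo = (Fm - Fj) / (Fm - Fo)   probability a trapped exciton moves
                                     an electron past QA-
    RC_QA  = phi_Po * (Vj/Mo) * (ABS/CS)  density of QA-reducing centres
    delta_Ro = (Fm - Fi) / (Fm - Fj) PQ -> PSI-end transfer efficiency

ABS/CS (absorbed photon flux per cross-section) defaults to the Fo
proxy, the usual ABS/CS_o convention, and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorTransient",
    "Marks",
    "JIPParameters",
    "MARK_TIMES",
    "extract_marks",
    "compute_jip",
    "compare_groups",
    "read_transient_csv",
]

# mark name -> (time in seconds, nominal acquisition step in seconds)
MARK_TIMES = {
    "fo": (50e-6, 10e-6),
    "fk": (300e-6, 10e-6),
    "fj": (2e-3, 10e-6),
    "fi": (30e-3, 1e-3),
}


@dataclass
class FluorTransient:
    """A fluorescence induction trace: time in seconds (strictly
    increasing) and intensity in instrument units."""

    time: np.ndarray
    F: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape or self.time.ndim != 1:
            raise ValueError("time and F must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("a transient needs at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class Marks:
    fo: float
    fk: float
    fj: float
    fi: float
    fm: float
    interpolated: frozenset = field(default_factory=frozenset)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.fo, self.fk, self.fj, self.fi, self.fm)


@dataclass(frozen=True)
class JIPParameters:
    fo: float
    fk: float
    fj: float
    fi: float
    fm: float
    vj: float
    mo: float
    wk: float
    phi_po: float
    phi_eo: float
    psi_eo: float
    rc_qa: float
    delta_ro: float
    abs_cs: float

    RATIO_FIELDS = (
        "vj", "mo", "wk", "phi_po", "phi_eo", "psi_eo", "delta_ro",
    )


def _value_at(transient: FluorTransient, t: float, half_step: float, name: str):
    """Nearest-sample lookup at time t, falling back to linear
    interpolation when no sample lies within half a grid step."""
    time, F = transient.time, transient.F
    if t < time[0] or t > time[-1]:
        raise ValueError(
            f"mark {name} at {t:g} s lies outside the trace span "
            f"[{time[0]:g}, {time[-1]:g}] s"
        )
    idx = int(np.argmin(np.abs(time - t)))
    if abs(time[idx] - t) <= half_step:
        return float(F[idx]), False
    return float(np.interp(t, time, F)), True


def extract_marks(transient: FluorTransient) -> Marks:
    """Read Fo, Fk, Fj, Fi at their defining time points (50 us, 300 us,
    2 ms, 30 ms) and Fm as the trace maximum."""
    values = {}
    interpolated = set()
    for name, (t, step) in MARK_TIMES.items():
        values[name], was_interp = _value_at(transient, t, step / 2.0, name)
        if was_interp:
            interpolated.add(name)
    return Marks(
        fo=values["fo"],
        fk=values["fk"],
        fj=values["fj"],
        fi=values["fi"],
        fm=float(np.max(transient.F)),
        interpolated=frozenset(interpolated),
    )


def compute_jip(marks: Marks, abs_cs: Optional[float] = None) -> JIPParameters:
    """Derive the JIP-test parameters from the five marks.

    ``abs_cs`` defaults to Fo (the ABS/CS_o proxy).  A flat transient
    (Fm = Fo) has no variable fluorescence and is rejected; Fj = Fo
    leaves Wk undefined (NaN, with a warning), and Mo = 0 leaves RC_QA
    undefined.
    """
    fo, fk, fj, fi, fm = marks.as_tuple()
    if fm <= fo:
        raise ValueError("no variable fluorescence (Fm <= Fo)")
    if abs_cs is None:
        abs_cs = fo

    fv = fm - fo
    vj = (fj - fo) / fv
    mo = 4.0 * (fk - fo) / fv
    phi_po = 1.0 - fo / fm
    phi_eo = (fm - fj) / fm
    psi_eo = (fm - fj) / fv
    delta_ro = (fm - fi) / (fm - fj) if fj != fm else float("nan")

    if fj == fo:
        warnings.warn("Fj equals Fo: Wk is undefined")
        wk = float("nan")
    else:
        wk = (fk - fo) / (fj - fo)

    if mo == 0.0:
        warnings.warn("Mo is zero: RC_QA is undefined")
        rc_qa = float("nan")
    else:
        rc_qa = phi_po * (vj / mo) * abs_cs

    return JIPParameters(
        fo=fo, fk=fk, fj=fj, fi=fi, fm=fm,
        vj=vj, mo=mo, wk=wk,
        phi_po=phi_po, phi_eo=phi_eo, psi_eo=psi_eo,
        rc_qa=rc_qa, delta_ro=delta_ro, abs_cs=abs_cs,
    )


_COMPARE_FIELDS = (
    "wk", "rc_qa", "phi_po", "phi_eo", "psi_eo", "delta_ro", "vj", "mo",
)


def compare_groups(
    control: Sequence[JIPParameters], treatment: Sequence[JIPParameters]
) -> pd.DataFrame:
    """Per-parameter mean, standard error and percent difference
    (100 x (treatment - control) / control) between two replicate groups."""

    def stats(group, name):
        vals = np.array([getattr(p, name) for p in group], dtype=float)
        mean = float(np.mean(vals))
        se = (
            float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1
            else float("nan")
        )
        return mean, se

    rows = []
    for name in _COMPARE_FIELDS:
        mc, sc = stats(control, name)
        mt, st = stats(treatment, name)
        pct = 100.0 * (mt - mc) / mc if mc != 0 else float("nan")
        rows.append(
            {
                "parameter": name,
                "mean_control": mc,
                "se_control": sc,
                "mean_treatment": mt,
                "se_treatment": st,
                "pct_difference": pct,
            }
        )
    return pd.DataFrame(rows)


def read_transient_csv(path, label: str = "") -> FluorTransient:
    """Read a 2-column CSV (time_s, F) into a transient."""
    df = pd.read_csv(path)
    return FluorTransient(
        time=df.iloc[:, 0].to_numpy(), F=df.iloc[:, 1].to_numpy(), label=label
    )


def read_transients_csv(path) -> list[FluorTransient]:
    """Read a multi-trace CSV (time_s, then one column per replicate)
    into a list of transients, one per replicate column."""
    df = pd.read_csv(path)
    time = df.iloc[:, 0].to_numpy()
    return [
        FluorTransient(time=time, F=df[col].to_numpy(), label=str(col))
        for col in df.columns[1:]
    ]
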