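"""Growth-curve and reporter-kinetics metrics for bacterial strain comparison.

Quantifies the fitness and translation phenotypes of rRNA point mutants from
plate-reader time series (OD600 and fluorescent-reporter signal sampled at
fixed intervals, typically 30 min). The per-interval protein production rate
is r_t = (F_t - F_{t-1}) / OD_t; the maximal production rate is the peak of
that series and total production the area under it. Growth rate is the
maximal sliding-window slope of ln(OD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class KineticsTable:
    """One replicate's time series: minutes, OD600 and optional fluorescence."""

    time: np.ndarray
    od: np.ndarray
    fluo: np.ndarray | None = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.fluo is not None:
            self.fluo = np.asarray(self.fluo, dtype=float)
            if self.fluo.shape != self.time.shape:
                raise ValueError("fluo and time must have the same length")
        if self.od.shape != self.time.shape:
            raise ValueError("od and time must have the same length")
        if len(self.time) and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.time, "od": self.od}
        if self.fluo is not None:
            d["fluo"] = self.fluo
        df = pd.DataFrame(d)
        df["replicate"] = self.replicate_id
        return df


@dataclass
class KineticsSummary:
    max_production_rate: float
    total_production: float
    max_growth_rate: float                       # 1/min
    relative_to_reference: dict[str, float] = field(default_factory=dict)  # percentages


def production_rate(table: KineticsTable) -> np.ndarray:
    """Per-interval reporter production rate r_t = (F_t - F_{t-1}) / OD_t.

    The series has length n-1 and is indexed by the interval's right
    endpoint (t >= 2).
    """
    if table.fluo is None:
        raise ValueError("table has no fluorescence column")
    if len(table) < 2:
        raise ValueError("need at least two time points")
    od_t = table.od[1:]
    if np.any(od_t <= 0):
        raise ValueError("OD must be positive wherever a rate is computed")
    return np.diff(table.fluo) / od_t


def max_growth_rate(table: KineticsTable, window: int = 5) -> float:
    """Maximal slope of ln(OD) over a sliding window of ``window`` points."""
    if len(table) < window:
        raise ValueError(f"need at least {window} time points")
    if np.any(table.od <= 0):
        raise ValueError("OD must be positive for log growth rate")
    log_od = np.log(table.od)
    best = -np.inf
    for i in range(len(table) - window + 1):
        t = table.time[i:i + window]
        y = log_od[i:i + window]
        slope = np.polyfit(t, y, 1)[0]
        best = max(best, slope)
    return float(best)


def summarize(
    table: KineticsTable,
    reference: KineticsSummary | None = None,
    growth_window: int = 5,
) -> KineticsSummary:
    """Summary metrics, optionally expressed relative to a reference strain.

    Total production integrates the raw (unsmoothed) rate series by the
    trapezoid rule on the time grid. Relative metrics are percentages of
    the reference's value.
    """
    r = production_rate(table)
    total = float(np.trapezoid(r, table.time[1:]))
    summary = KineticsSummary(
        max_production_rate=float(np.max(r)),
        total_production=total,
        max_growth_rate=max_growth_rate(table, window=growth_window))
    if reference is not None:
        rel = {}
        for name in ("max_production_rate", "total_production", "max_growth_rate"):
            ref_val = getattr(reference, name)
            if ref_val == 0:
                raise ValueError(f"reference {name} is zero; relative metric undefined")
            rel[name] = 100.0 * getattr(summary, name) / ref_val
        summary.relative_to_reference = rel
    return summary


def average_curves(tables: list[KineticsTable]) -> pd.DataFrame:
    """Pointwise mean and sample standard deviation across replicates.

    All replicates must share an identical time grid (plates are read on a
    common schedule). Columns: time, od_mean, od_sd and, when every
    replicate has fluorescence, fluo_mean, fluo_sd.
    """
    if not tables:
        raise ValueError("no replicates given")
    t0 = tables[0].time
    for t in tables[1:]:
        if len(t.time) != len(t0) or not np.allclose(t.time, t0):
            raise ValueError("replicates have mismatched time grids")
    od = np.vstack([t.od for t in tables])
    out = {"time": t0, "od_mean": od.mean(axis=0),
           "od_sd": od.std(axis=0, ddof=1) if len(tables) > 1 else np.zeros_like(t0)}
    if all(t.fluo is not None for t in tables):
        fl = np.vstack([t.fluo for t in tables])
        out["fluo_mean"] = fl.mean(axis=0)
        out["fluo_sd"] = fl.std(axis=0, ddof=1) if len(tables) > 1 else np.zeros_like(t0)
    return pd.DataFrame(out)


def read_kinetics_tsv(path) -> list[KineticsTable]:
    """Read replicate time series from TSV (columns: time, od[, fluo], replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time", "od"}
    if not required <= set(df.columns):
        raise ValueError(f"TSV must contain columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = "rep1"
    tables = []
    for rep, grp in df.groupby("replicate", sort=True):
        grp = grp.sort_values("time")
        tables.append(KineticsTable(
            time=grp["time"].to_numpy(),
            od=grp["od"].to_numpy(),
            fluo=grp["fluo"].to_numpy() if "fluo" in grp.columns else None,
            replicate_id=str(rep)))
    return tables


def write_kinetics_tsv(path, tables: list[KineticsTable]) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, sep="\t", index=False)
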