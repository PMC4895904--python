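"""Stochastic stability classification of toggle-switch trajectories.

The state of the switch is summarized by the integer series
Delta = (active LacI-class count) - (active TetR-class count); by default
the active species are the free, inducer-free LacI tetramer and TetR dimer.
Two long simulations are run per condition, one started with an excess of
each repressor (400 molecules), and the Delta histograms decide the class:

* monostable - for both starts, more than 95 % of the samples lie on one
  and the same side of zero;
* bistable   - the two histograms occupy disjoint integer bins (no
  switching observed within the simulated span);
* joint bistable - anything else: two distinguishable states with observed
  stochastic switching; the switching frequency is the mean zero-crossing
  rate of the two runs.

A switch is a strict sign change of Delta between consecutive samples;
zero-valued samples inherit the preceding sign.  Heat maps over the
[IPTG] x [DOX] plane and histogram stacks along inducer titration paths
reproduce the circuit's phase-diagram readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .grid import PhaseGrid
from .network import LITRConfig, build_litr_network
from .ssa import Trajectory, simulate

__all__ = [
    "DEFAULT_AGGREGATION",
    "DeltaSeries",
    "SwitchStats",
    "ClassificationResult",
    "delta_series",
    "count_switches",
    "classify",
    "classify_litr",
    "stability_heatmap",
    "titration_histograms",
    "cell_seed",
]

#: free, inducer-free active species; DNA- and inducer-bound forms excluded
DEFAULT_AGGREGATION = (("LacI4",), ("TetR2",))


@dataclass
class DeltaSeries:
    """Integer difference series between the two active-species counts."""

    sample_times: np.ndarray
    delta: np.ndarray
    aggregation: tuple[tuple[str, ...], tuple[str, ...]]

    def __len__(self):
        return len(self.delta)


class SwitchStats(NamedTuple):
    crossings: int
    frequency_hz: float
    degenerate: bool  # all-zero series: no sign ever established


def delta_series(trajectory: Trajectory,
                 aggregation: tuple[Sequence[str], Sequence[str]]
                 = DEFAULT_AGGREGATION) -> DeltaSeries:
    """Delta(t) = sum of gene-1 active counts - sum of gene-2 active counts."""
    side_a, side_b = aggregation
    for name in tuple(side_a) + tuple(side_b):
        if name not in trajectory.species:
            raise ValueError(f"aggregation species {name!r} not in trajectory "
                             f"(has {trajectory.species})")
    a = sum(trajectory.species_series(s).astype(np.int64) for s in side_a)
    b = sum(trajectory.species_series(s).astype(np.int64) for s in side_b)
    return DeltaSeries(sample_times=trajectory.sample_times, delta=a - b,
                       aggregation=(tuple(side_a), tuple(side_b)))


def count_switches(series: DeltaSeries) -> SwitchStats:
    """Count strict zero crossings of Delta and the crossing rate in Hz.

    Zero samples inherit the sign of the last nonzero sample; leading zeros
    carry no sign and cannot produce a crossing.  The rate divides by the
    observation span (last minus first sample time).
    """
    d = np.asarray(series.delta)
    if len(d) == 0:
        raise ValueError("empty Delta series")
    sign = np.sign(d)
    nz = sign != 0
    if not np.any(nz):
        return SwitchStats(0, 0.0, True)
    # propagate the last nonzero sign forward over zero samples; leading
    # zeros stay signless and cannot participate in a crossing
    idx = np.where(nz, np.arange(len(d)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0)
    changes = int(np.sum((filled[1:] != filled[:-1]) & (filled[:-1] != 0)))
    span = float(series.sample_times[-1] - series.sample_times[0])
    freq = changes / span if span > 0 else 0.0
    return SwitchStats(changes, freq, False)


@dataclass
class ClassificationResult:
    """Stability class of one circuit condition from a pair of runs."""

    stability_class: str          # monostable_gene1|monostable_gene2|bistable|joint_bistable
    switching_frequency_hz: float
    histogram_a: dict[int, int]   # Delta histogram, gene-1-high start
    histogram_b: dict[int, int]   # Delta histogram, gene-2-high start
    crossings_a: int = 0
    crossings_b: int = 0

    def __post_init__(self):
        if self.switching_frequency_hz < 0:
            raise ValueError("switching frequency must be >= 0")


def _histogram(d: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(d, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def classify(run_a: DeltaSeries, run_b: DeltaSeries,
             burn_in_frac: float = 0.01,
             monostable_threshold: float = 0.95) -> ClassificationResult:
    """Classify a condition from its two oppositely initialized runs.

    ``run_a`` must start gene-1 (LacI) high and ``run_b`` gene-2 (TetR)
    high.  The first ``burn_in_frac`` of the samples is discarded so the
    artificial initial excess does not enter the histograms (0 reproduces
    the literal histogram-of-everything reading).  Exactly reaching the
    monostable threshold does not count as monostable (strict >).
    """
    if len(run_a) == 0 or len(run_b) == 0:
        raise ValueError("empty Delta series")
    out = []
    for run in (run_a, run_b):
        burn = int(np.floor(burn_in_frac * len(run)))
        d = run.delta[burn:]
        if len(d) == 0:
            raise ValueError("burn-in removed every sample")
        out.append((d, replace(run, sample_times=run.sample_times[burn:],
                               delta=d)))
    (da, sa), (db, sb) = out
    frac_pos = [float(np.mean(d > 0)) for d in (da, db)]
    frac_neg = [float(np.mean(d < 0)) for d in (da, db)]
    hist_a, hist_b = _histogram(da), _histogram(db)
    no_switching = (count_switches(sa).crossings == 0
                    and count_switches(sb).crossings == 0)
    if min(frac_pos) > monostable_threshold:
        cls, freq = "monostable_gene1", 0.0
    elif min(frac_neg) > monostable_threshold:
        cls, freq = "monostable_gene2", 0.0
    elif not set(hist_a) & set(hist_b) and no_switching:
        # strict (disjoint) bistability: no crossing observed anywhere and
        # the two histograms share no occupied bin
        cls, freq = "bistable", 0.0
    else:
        cls = "joint_bistable"
        freq = 0.5 * (count_switches(sa).frequency_hz
                      + count_switches(sb).frequency_hz)
    return ClassificationResult(
        stability_class=cls, switching_frequency_hz=freq,
        histogram_a=hist_a, histogram_b=hist_b,
        crossings_a=count_switches(sa).crossings,
        crossings_b=count_switches(sb).crossings)


# ---------------------------------------------------------------------------
# LITR drivers
# ---------------------------------------------------------------------------

_SPLITMIX_GAMMA = 0x9E3779B97F4A7C15
_M64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + _SPLITMIX_GAMMA) & _M64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _M64
    return (x ^ (x >> 31)) & _M64


def cell_seed(base_seed: int, i: int, j: int, init: int) -> int:
    """Stable per-cell, per-initialization seed derived from a base seed."""
    h = _splitmix64(_splitmix64(_splitmix64(i) ^ j * 0x632BE59BD9B4E019) ^ init)
    return (base_seed ^ h) & 0x7FFFFFFFFFFFFFFF


def classify_litr(config: LITRConfig,
                  t_end: float = 1e5,
                  sample_dt: float = 1.0,
                  seed_a: int = 1,
                  seed_b: int = 2,
                  excess: int = 400,
                  aggregation=DEFAULT_AGGREGATION,
                  burn_in_frac: float = 0.01) -> ClassificationResult:
    """Simulate both initializations of a LITR condition and classify.

    Run A starts with ``excess`` LacI tetramers, run B with ``excess`` TetR
    dimers, all other non-constant species at zero (promoters free).
    """
    network = build_litr_network(config)
    tr_a = simulate(network.with_initial_counts({"LacI4": excess}),
                    t_end, sample_dt, seed_a)
    tr_b = simulate(network.with_initial_counts({"TetR2": excess}),
                    t_end, sample_dt, seed_b)
    return classify(delta_series(tr_a, aggregation),
                    delta_series(tr_b, aggregation),
                    burn_in_frac=burn_in_frac)


def stability_heatmap(iptg_values: Sequence[float],
                      dox_values: Sequence[float],
                      config: LITRConfig,
                      t_end: float = 1e5,
                      sample_dt: float = 1.0,
                      base_seed: int = 0,
                      **classify_kw) -> PhaseGrid:
    """Stochastic stability classes and switching frequencies over a grid.

    Per-cell seeds derive from ``base_seed`` and the cell index so the map
    is reproducible and cells are independent.  Cells whose simulation
    fails are marked ``unknown``.
    """
    iptg_values = np.asarray(list(iptg_values), dtype=float)
    dox_values = np.asarray(list(dox_values), dtype=float)
    classes = np.empty((len(iptg_values), len(dox_values)), dtype=object)
    freq = np.zeros(classes.shape)
    seeds = {}
    for i, iptg in enumerate(iptg_values):
        for j, dox in enumerate(dox_values):
            cfg = replace(config, iptg=float(iptg), dox=float(dox))
            sa = cell_seed(base_seed, i, j, 0)
            sb = cell_seed(base_seed, i, j, 1)
            seeds[(i, j)] = (sa, sb)
            try:
                res = classify_litr(cfg, t_end=t_end, sample_dt=sample_dt,
                                    seed_a=sa, seed_b=sb, **classify_kw)
                classes[i, j] = res.stability_class
                freq[i, j] = res.switching_frequency_hz
            except Exception:
                classes[i, j] = "unknown"
                freq[i, j] = 0.0
    return PhaseGrid(axis1_name="iptg_nM", axis1_values=iptg_values,
                     axis2_name="dox_nM", axis2_values=dox_values,
                     classes=classes, frequency=freq,
                     cell_meta={"seeds": seeds, "t_end_s": t_end,
                                "sample_dt_s": sample_dt,
                                "base_seed": base_seed})


def titration_histograms(path: Sequence[tuple[float, float, float]],
                         config: LITRConfig,
                         t_end: float = 1e5,
                         sample_dt: float = 1.0,
                         base_seed: int = 0,
                         **classify_kw):
    """Delta histograms along an inducer-space titration path.

    ``path`` lists (t, iptg_nM, dox_nM) points with monotone t in [0, 1]
    (t is the fractional position along the path).  Each point runs a fresh
    pair of simulations; the two runs' histograms are summed and normalized
    to the largest bin across the whole set.  Returns a long-format
    DataFrame (t, delta_bin, normalized_count, stability_class).
    """
    import pandas as pd
    if len(path) == 0:
        raise ValueError("titration path is empty")
    ts = [p[0] for p in path]
    if any(t1 > t2 for t1, t2 in zip(ts, ts[1:])) or \
            any(not 0 <= t <= 1 for t in ts):
        raise ValueError("path positions t must be monotone within [0, 1]")
    rows = []
    for idx, (t, iptg, dox) in enumerate(path):
        cfg = replace(config, iptg=float(iptg), dox=float(dox))
        res = classify_litr(cfg, t_end=t_end, sample_dt=sample_dt,
                            seed_a=cell_seed(base_seed, idx, 0, 0),
                            seed_b=cell_seed(base_seed, idx, 0, 1),
                            **classify_kw)
        merged: dict[int, int] = dict(res.histogram_a)
        for k, v in res.histogram_b.items():
            merged[k] = merged.get(k, 0) + v
        for bin_, count in sorted(merged.items()):
            rows.append({"t": t, "iptg_nM": iptg, "dox_nM": dox,
                         "delta_bin": bin_, "count": count,
                         "stability_class": res.stability_class})
    df = pd.DataFrame(rows)
    df["normalized_count"] = df["count"] / df["count"].max()
    return df
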