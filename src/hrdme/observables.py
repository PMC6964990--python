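"""Post-processing: ensemble statistics, rebind times, series errors.

The quantities here are the ones the hierarchical solver is judged by:

* ensemble mean/SD copy-number time series over many trajectories;
* the distribution of *rebinding times* — the interval between a
  dissociation and the next association of the reversible pair, the
  fine-scale statistic a coarse mesh destroys and the hierarchy must
  preserve;
* a scalar trajectory error between a test and a reference mean series;
* endpoint count densities (histograms at a fixed time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory
from .model import ReactionModel

__all__ = [
    "EnsembleSeries",
    "RebindSample",
    "ensemble_series",
    "collect_rebinds",
    "series_error",
    "endpoint_density",
]


@dataclass
class EnsembleSeries:
    """Per-trajectory copy numbers of one species on a common time grid."""

    times: np.ndarray            # (T,)
    counts: np.ndarray           # (n_traj, T) nonnegative integers
    species: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.times.size:
            raise ValueError("counts must be (n_traj, n_times)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1)

    def at_time(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t):
            raise ValueError(f"t={t} is not on the sample grid")
        return self.counts[:, i]

    def write_tsv(self, path: str, header_comment: str | None = None) -> None:
        df = pd.DataFrame({"time": self.times, "mean": self.mean, "sd": self.sd})
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)


def ensemble_series(trajectories: Sequence[Trajectory], species: str) -> EnsembleSeries:
    """Stack one species' counts from trajectories sharing a sample grid."""
    t0 = trajectories[0].times
    for tr in trajectories[1:]:
        if not np.array_equal(tr.times, t0):
            raise ValueError("trajectories have mismatched sample grids")
    col = trajectories[0].species.index(species)
    counts = np.stack([tr.counts[:, col] for tr in trajectories])
    return EnsembleSeries(t0.copy(), counts, species)


@dataclass
class RebindSample:
    """Dissociation-to-next-association durations of a tracked pair."""

    durations: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.size and np.any(self.durations <= 0):
            raise ValueError("rebind durations must be positive")

    def __len__(self) -> int:
        return int(self.durations.size)

    def write_tsv(self, path: str, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("rebind_time\n")
            np.savetxt(fh, self.durations, fmt="%.10g")


def collect_rebinds(event_log: pd.DataFrame, model: ReactionModel) -> RebindSample:
    """Extract rebind times from a reaction event log.

    The model must contain exactly one reversible pair ``A + B <-> AB``
    with at most one pair instance alive at any time (otherwise the
    dissociation/association pairing is ambiguous and the function
    refuses).  For every dissociation at ``t_d`` followed by an
    association at ``t_a`` the duration ``t_a - t_d`` is collected; a
    trailing dissociation without a re-association contributes nothing.
    """
    assoc, dissoc = _reversible_pair(model)
    n_pairs = model.initial.get(assoc.products[0], 0) + min(
        model.initial.get(assoc.reactants[0], 0),
        model.initial.get(assoc.reactants[1], 0),
    )
    if n_pairs != 1:
        raise ValueError(
            "rebind collection needs exactly one tracked pair in the system "
            f"(found {n_pairs}); multiple simultaneous pairs are ambiguous")
    ia = model.reactions.index(assoc)
    idx = model.reactions.index(dissoc)
    ev = event_log[event_log["channel"].isin([ia, idx])]
    times = ev["time"].to_numpy()
    chans = ev["channel"].to_numpy()
    out = []
    t_d = None
    for t, c in zip(times, chans):
        if c == idx:
            t_d = t
        elif t_d is not None:
            out.append(t - t_d)
            t_d = None
    return RebindSample(np.asarray(out))


def _reversible_pair(model: ReactionModel):
    """The unique (association, dissociation) channel pair of the model."""
    pairs = []
    for a in model.bimolecular_channels():
        for d in model.reactions:
            if d.order == 1 and sorted(d.products) == sorted(a.reactants) \
                    and list(a.products) == list(d.reactants):
                pairs.append((a, d))
    if len(pairs) != 1:
        raise ValueError(f"expected exactly one reversible pair, found {len(pairs)}")
    return pairs[0]


def series_error(test: EnsembleSeries, reference: EnsembleSeries,
                 normalized: bool = True) -> float:
    """Summed absolute difference of the mean series.

    ``E = sum_i |mean_test(t_i) - mean_ref(t_i)| / sum_i mean_ref(t_i)``
    when ``normalized`` (the relative form); the bare sum otherwise.  The
    numerator is symmetric, so E is a pseudometric on mean series: zero
    exactly when the means agree on the grid.
    """
    if test.times.shape != reference.times.shape or \
            not np.allclose(test.times, reference.times):
        raise ValueError("mismatched sample grids")
    num = float(np.abs(test.mean - reference.mean).sum())
    if not normalized:
        return num
    den = float(reference.mean.sum())
    if den == 0.0:
        raise ValueError("reference series sums to zero; relative error undefined")
    return num / den


def endpoint_density(trajectories: Sequence[Trajectory], species: str,
                     t: float) -> tuple[pd.DataFrame, float, float]:
    """Empirical distribution of a species count at time ``t``.

    Returns ``(histogram, mean, sd)`` where the histogram has integer bins
    (counts are integers) with their occurrence probabilities.
    """
    series = ensemble_series(trajectories, species)
    x = series.at_time(t)
    values, freq = np.unique(x, return_counts=True)
    hist = pd.DataFrame({"count": values.astype(int),
                         "probability": freq / x.size})
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return hist, float(x.mean()), sd
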