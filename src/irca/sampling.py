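"""Sampling-depth analysis: how many cells does IRCA need?

Correlations estimated from few cells are noisy; these routines quantify
the stability of cumulative IRCA traits as the number of sampled cells
("depth") grows, by repeated random subsampling without replacement:

* cumPCC — the Pearson correlation between two chosen peaks (defaults
  938 and 2855 cm^-1, the starch / TAG pair) at each depth;
* cumAveDegree — the average degree of the strong-negative network built
  from a subsample at each depth.

The minimal sampling depth is the smallest depth from which adding one
more cell changes the trait by no more than a threshold (default 1%),
sustained for all larger evaluated depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from irca.core import DegenerateInputError, IrcaError, Ramanome

__all__ = [
    "DepthCurve", "cum_pcc", "cum_ave_degree", "gain_curve",
    "minimal_sampling_depth", "depth_curve",
]


@dataclass
class DepthCurve:
    """Mean/sd of a cumulative trait per sampling depth, plus gain."""

    depths: np.ndarray
    trait_mean: np.ndarray
    trait_sd: np.ndarray
    gain: np.ndarray          # relative change per added cell; gain[0] is NaN
    trait: str = ""
    n_perm: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=int)
        if d.size and d[0] < 3:
            raise IrcaError("depths must start at >= 3 (Pearson defined)")
        if np.any(np.diff(d) <= 0):
            raise IrcaError("depths must be strictly increasing")
        self.depths = d


def _subsample_indices(rng: np.random.Generator, n_cells: int,
                       depth: int) -> np.ndarray:
    # sorted: a subsample is a set of cells, and a canonical order keeps
    # full-depth draws bit-identical
    return np.sort(rng.choice(n_cells, size=depth, replace=False))


def cum_pcc(r: Ramanome, peak_a: float = 938.0, peak_b: float = 2855.0,
            depth: int = 10, n_perm: int = 1000,
            seed: int | np.random.Generator | None = None,
            ) -> tuple[float, float]:
    """Mean and sd of the two-peak Pearson correlation over random
    subsamples of ``depth`` cells.

    Subsampling is without replacement; a subsample in which either peak
    has zero variance is redrawn (logged via warning). At depth equal to
    the population size every subsample is the full population, so the
    sd is exactly 0.
    """
    if depth < 3:
        raise DegenerateInputError("depth must be >= 3")
    if depth > r.n_cells:
        raise IrcaError(f"depth {depth} exceeds n_cells {r.n_cells}")
    x = r.peak_column(peak_a)
    y = r.peak_column(peak_b)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vals = np.empty(n_perm)
    redraws = 0
    for i in range(n_perm):
        for _ in range(100):
            idx = _subsample_indices(rng, r.n_cells, depth)
            xs, ys = x[idx], y[idx]
            if xs.std() > 0 and ys.std() > 0:
                break
            redraws += 1
        else:
            raise IrcaError("could not draw a subsample with variance")
        vals[i] = np.corrcoef(xs, ys)[0, 1]
    if redraws:
        warnings.warn(f"{redraws} zero-variance subsamples redrawn",
                      stacklevel=2)
    sd = 0.0 if np.ptp(vals) == 0 else float(vals.std())
    return float(vals.mean()), sd


def cum_ave_degree(r: Ramanome, depth: int = 10, n_perm: int = 100,
                   rho_threshold: float = -0.6, alpha: float = 0.05,
                   seed: int | np.random.Generator | None = None,
                   features: list[str] | None = None,
                   ) -> tuple[float, float]:
    """Mean and sd of the strong-negative network's average degree over
    random subsamples of ``depth`` cells."""
    from irca.network import build_ircn, correlation_matrix, network_stats

    if depth < 3:
        raise DegenerateInputError("depth must be >= 3")
    if depth > r.n_cells:
        raise IrcaError(f"depth {depth} exceeds n_cells {r.n_cells}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vals = np.empty(n_perm)
    for i in range(n_perm):
        idx = _subsample_indices(rng, r.n_cells, depth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = correlation_matrix(r.matrix[idx], features)
        g = build_ircn(cm, "strong_negative", rho_threshold, alpha)
        vals[i] = network_stats(g).ave_degree
    sd = 0.0 if np.ptp(vals) == 0 else float(vals.std())
    return float(vals.mean()), sd


def gain_curve(trait_mean: np.ndarray) -> np.ndarray:
    """Relative change of the trait from each depth to the next.

    gain[d] = |T(d) - T(d-1)| / |T(d-1)|; the first entry is NaN (no
    predecessor). A zero predecessor makes the gain |T(d)| with a
    warning.
    """
    t = np.asarray(trait_mean, dtype=float)
    if t.size < 2:
        raise DegenerateInputError("gain needs >= 2 depths")
    gain = np.full(t.size, np.nan)
    prev = t[:-1]
    diff = np.abs(np.diff(t))
    zero = prev == 0
    if zero.any():
        warnings.warn("zero trait value; gain taken as |T(d)|", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = diff / np.abs(prev)
    rel[zero] = diff[zero]
    gain[1:] = rel
    return gain


def minimal_sampling_depth(curve: DepthCurve, threshold: float = 0.01,
                           sustained: bool = True) -> tuple[int, bool]:
    """Smallest depth from which the gain stays at or below ``threshold``.

    With ``sustained`` (default) the gain must remain under the threshold
    at every larger evaluated depth, which guards against noise-induced
    early stops; otherwise the first crossing is reported. Returns
    (depth, reached); when no depth qualifies, (max depth, False).
    """
    g = curve.gain
    ok = g[1:] <= threshold  # gains defined from the second depth on
    if sustained:
        qualifying = [i for i in range(ok.size) if ok[i:].all()]
    else:
        qualifying = [i for i in range(ok.size) if ok[i]]
    if not qualifying:
        return int(curve.depths[-1]), False
    return int(curve.depths[qualifying[0] + 1]), True


def depth_curve(r: Ramanome, trait: str = "cumpcc",
                depths: np.ndarray | None = None,
                peak_a: float = 938.0, peak_b: float = 2855.0,
                n_perm: int = 1000, seed: int | None = None,
                rho_threshold: float = -0.6, alpha: float = 0.05,
                ) -> DepthCurve:
    """Evaluate a cumulative trait over a grid of sampling depths.

    ``trait`` is 'cumpcc' or 'cumavedegree'. Depths default to every
    integer from 3 to n_cells, honoring the one-more-cell definition of
    the gain.
    """
    if depths is None:
        depths = np.arange(3, r.n_cells + 1)
    depths = np.asarray(depths, dtype=int)
    rng = np.random.default_rng(seed)
    means = np.empty(depths.size)
    sds = np.empty(depths.size)
    for i, d in enumerate(depths):
        if trait == "cumpcc":
            means[i], sds[i] = cum_pcc(r, peak_a, peak_b, int(d),
                                       n_perm, rng)
        elif trait == "cumavedegree":
            means[i], sds[i] = cum_ave_degree(r, int(d), n_perm,
                                              rho_threshold, alpha, rng)
        else:
            raise IrcaError(f"unknown trait {trait!r}")
    return DepthCurve(depths=depths, trait_mean=means, trait_sd=sds,
                      gain=gain_curve(means), trait=trait,
                      n_perm=n_perm, seed=seed)
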