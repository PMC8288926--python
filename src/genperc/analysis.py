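"""Monte Carlo protocols for generational percolation.

Ensemble sweeps of the order parameter over a control grid, per-realization
order-parameter distributions and their bimodal split into percolating and
non-percolating realizations, pseudo-critical detection via the peak of the
mean second-largest cluster, pooled cluster-size distributions, and the two
finite-size-scaling fits used to classify the transitions:

* continuous transitions — pure power-law decay psi_c ∝ N^(-eps), with
  eps = 1/3 for random networks;
* discontinuous transitions — offset form psi_c = psi_c0 + O(N^(-eps)),
  fitted over percolating realizations only, with a nonzero limit psi_c0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import MultiplexNetwork, edge_marks, occupy, percolate_generations
from .generators import er_multiplex, sf_multiplex

__all__ = [
    "GeneratorSpec",
    "ERSpec",
    "SFSpec",
    "SweepResult",
    "ScalingFit",
    "ensemble_sweep",
    "order_parameter_samples",
    "classify_percolating",
    "pseudo_critical_point",
    "two_stage_pseudo_critical",
    "fit_power_scaling",
    "fit_offset_scaling",
    "cluster_size_distribution",
]


@dataclass(frozen=True)
class ERSpec:
    """Two-layer ER ensemble at average degree z per layer."""

    n_nodes: int
    z: float

    def build(self, rng) -> MultiplexNetwork:
        return er_multiplex(self.n_nodes, self.z, rng)


@dataclass(frozen=True)
class SFSpec:
    """Two-layer truncated power-law configuration-model ensemble."""

    n_nodes: int
    gamma: float = 2.5
    m: int = 2
    K: int | None = None  # None -> floor(sqrt(N))

    def build(self, rng) -> MultiplexNetwork:
        return sf_multiplex(self.n_nodes, self.gamma, self.m, self.K, rng)


GeneratorSpec = ERSpec | SFSpec


@dataclass
class SweepResult:
    """Ensemble sweep over a control grid.

    ``psi[g][i, r]`` is the order parameter of realization r at grid point i
    for the g-th requested generation; ``n2`` holds second-largest cluster
    sizes (nodes) at the last requested generation.
    """

    control: str
    grid: np.ndarray
    generations: list[int]
    psi: dict[int, np.ndarray]
    n2: np.ndarray
    n_nodes: int
    n_realizations: int
    seed: int

    def mean_psi(self, generation: int) -> np.ndarray:
        return self.psi[generation].mean(axis=1)

    def mean_n2(self) -> np.ndarray:
        return self.n2.mean(axis=1)


@dataclass
class ScalingFit:
    """Log-log or offset power-law fit over system sizes."""

    sizes: np.ndarray
    values: np.ndarray
    exponent: float
    exponent_se: float
    offset: float | None = None
    amplitude: float | None = None
    residual: float | None = None
    fit_window: tuple[int, int] | None = None


def _resolve_generations(generations) -> tuple[list[int], bool]:
    """Split requested generations into finite list + steady-state flag."""
    gens, steady = [], False
    for g in generations:
        if g is None or g == np.inf or (isinstance(g, str) and g in ("inf", "steady")):
            steady = True
        else:
            gens.append(int(g))
    return sorted(gens), steady


def _run_realization(net: MultiplexNetwork, gens: list[int], steady: bool):
    """psi per requested generation (+ steady state) and final N2."""
    n_max = 100_000 if steady else max(gens)
    trace = percolate_generations(net, max_generations=n_max,
                                  stop_at_steady=True, keep_histograms=False)
    out = {g: trace.psi_at(g) for g in gens}
    if steady:
        out["steady"] = trace.final_psi()
    n2 = trace.second_largest[min(max(gens), len(trace.second_largest)) - 1] if gens \
        else trace.second_largest[-1]
    return out, n2


def ensemble_sweep(
    spec: GeneratorSpec,
    grid: Sequence[float],
    generations: Sequence = (1,),
    n_realizations: int = 20,
    seed: int = 0,
    control: str = "p",
    coupled: bool = True,
) -> SweepResult:
    """Sweep the control parameter over ``grid`` with R independent
    realizations per point.

    ``control='p'`` (occupation): each realization builds one multiplex from
    ``spec`` and dilutes it along the grid.  With ``coupled=True`` every
    edge carries a single uniform mark and the occupied sets {mark < p} are
    nested across the grid, which makes each realization's sweep monotone;
    ``coupled=False`` redraws the dilution at every grid point.
    ``control='z'`` (average degree, ER only): fresh layers are generated at
    every grid value.
    """
    grid = np.asarray(grid, dtype=float)
    gens, steady = _resolve_generations(generations)
    keys = gens + (["steady"] if steady else [])
    psi = {g: np.empty((len(grid), n_realizations)) for g in keys}
    n2 = np.empty((len(grid), n_realizations))
    master = np.random.SeedSequence(seed)
    for r, child in enumerate(master.spawn(n_realizations)):
        rng = np.random.default_rng(child)
        if control == "p":
            net = spec.build(rng)
            marks = edge_marks(net, rng.integers(2**31))
            for i, p in enumerate(grid):
                sub = occupy(net, marks, p) if coupled else _redraw(net, p, rng)
                res, second = _run_realization(sub, gens, steady)
                for g in keys:
                    psi[g][i, r] = res[g]
                n2[i, r] = second
        elif control == "z":
            if not isinstance(spec, ERSpec):
                raise ValueError("degree control is defined for the ER ensemble")
            for i, z in enumerate(grid):
                net = er_multiplex(spec.n_nodes, z, rng)
                res, second = _run_realization(net, gens, steady)
                for g in keys:
                    psi[g][i, r] = res[g]
                n2[i, r] = second
        else:
            raise ValueError("control must be 'p' or 'z'")
    return SweepResult(control=control, grid=grid, generations=keys, psi=psi,
                       n2=n2, n_nodes=spec.n_nodes, n_realizations=n_realizations,
                       seed=seed)


def _redraw(net: MultiplexNetwork, p: float, rng) -> MultiplexNetwork:
    from .core import dilute

    return dilute(net, p, int(rng.integers(2**31)))


def order_parameter_samples(
    spec: GeneratorSpec,
    control_value: float | None = None,
    generation=None,
    n_realizations: int = 100,
    seed: int = 0,
    control: str = "z",
) -> np.ndarray:
    """R per-realization largest-cluster fractions at one control value.

    ``generation=None`` (or 'steady') samples the steady state n = infinity;
    an integer samples that finite generation.  Degree control builds fresh
    ER layers at z = control_value; occupation control dilutes the spec's
    fixed ensemble at p = control_value.
    """
    gens, steady = _resolve_generations([generation])
    if not gens and not steady:
        steady = True
    master = np.random.SeedSequence(seed)
    out = np.empty(n_realizations)
    for r, child in enumerate(master.spawn(n_realizations)):
        rng = np.random.default_rng(child)
        if control == "z":
            if not isinstance(spec, ERSpec):
                raise ValueError("degree control is defined for the ER ensemble")
            net = er_multiplex(spec.n_nodes, control_value, rng)
        else:
            net = spec.build(rng)
            marks = edge_marks(net, int(rng.integers(2**31)))
            net = occupy(net, marks, control_value)
        res, _ = _run_realization(net, gens, steady)
        out[r] = res["steady"] if steady else res[gens[-1]]
    return out


def classify_percolating(
    samples: np.ndarray, n_nodes: int, n_bins: int = 30, fallback_c: float = 5.0
) -> tuple[np.ndarray, float]:
    """Split a bimodal order-parameter sample set into percolating and
    non-percolating realizations.

    The cutoff is the deepest histogram valley between the two most
    populated local modes; when the histogram shows no interior valley the
    cutoff falls back to ``fallback_c * N^(-1/3)`` (the continuous-transition
    finite-size scale).  Returns (boolean mask of percolating samples,
    percolating fraction).
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 20:
        raise ValueError("need at least 20 samples to classify")
    counts, edges = np.histogram(samples, bins=n_bins)
    # local maxima of the histogram (plateau-tolerant)
    peaks = [i for i in range(n_bins)
             if counts[i] > 0
             and (i == 0 or counts[i] >= counts[i - 1])
             and (i == n_bins - 1 or counts[i] > counts[i + 1])]
    cutoff = None
    if len(peaks) >= 2:
        order = sorted(peaks, key=lambda i: counts[i], reverse=True)[:2]
        lo, hi = sorted(order)
        if hi > lo + 1:
            valley = lo + 1 + int(np.argmin(counts[lo + 1: hi]))
            # a genuine bimodal valley is much emptier than the lesser mode;
            # shallow dips are histogram noise on a unimodal sample
            if counts[valley] <= 0.5 * min(counts[lo], counts[hi]):
                cand = 0.5 * (edges[valley] + edges[valley + 1])
                below, above = samples[samples <= cand], samples[samples > cand]
                # non-percolating realizations live near zero: demand a clear
                # scale separation, otherwise the split is histogram noise
                if len(below) and len(above) and below.mean() < 0.25 * above.mean():
                    cutoff = cand
    if cutoff is None:
        cutoff = fallback_c * n_nodes ** (-1.0 / 3.0)
    mask = samples > cutoff
    return mask, float(mask.mean())


def pseudo_critical_point(
    spec: GeneratorSpec,
    generation: int,
    grid: Sequence[float],
    n_realizations: int = 50,
    seed: int = 0,
    control: str = "p",
    sweep: SweepResult | None = None,
) -> float:
    """Finite-size pseudo-critical control value: the grid point maximizing
    the mean second-largest cluster, refined by quadratic interpolation
    through the argmax and its neighbours.  Raises if the peak sits on the
    grid boundary (grid too narrow)."""
    if sweep is None:
        sweep = ensemble_sweep(spec, grid, generations=[generation],
                               n_realizations=n_realizations, seed=seed,
                               control=control)
    mean_n2 = sweep.mean_n2()
    i = int(np.argmax(mean_n2))
    if i == 0 or i == len(mean_n2) - 1:
        raise ValueError("second-largest-cluster peak at grid boundary; widen the grid")
    x = sweep.grid[i - 1: i + 2]
    y = mean_n2[i - 1: i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom >= 0:  # flat or non-concave triple; keep the grid argmax
        return float(sweep.grid[i])
    shift = 0.5 * (y[0] - y[2]) / denom
    return float(x[1] + shift * (x[2] - x[1]))


def two_stage_pseudo_critical(
    spec: GeneratorSpec,
    generation: int,
    n_realizations: int,
    seed: int,
    coarse_grid: np.ndarray | None = None,
    coarse_realizations: int = 6,
    half_width: float = 0.05,
    step: float = 0.01,
) -> float:
    """Pseudo-critical occupation probability located in two stages.

    A coarse occupation sweep finds the approximate second-largest-cluster
    peak; a refined grid around it (half width ``half_width``, step
    ``step``) with ``n_realizations`` feeds the quadratic peak estimate.
    If the refined peak lands on the grid boundary the window is re-centred
    there and retried (at most twice) rather than returning a biased edge
    value.
    """
    if coarse_grid is None:
        coarse_grid = np.arange(0.05, 0.96, 0.05)
    sweep = ensemble_sweep(spec, coarse_grid, generations=[generation],
                           n_realizations=coarse_realizations, seed=seed,
                           control="p")
    center = float(coarse_grid[int(np.argmax(sweep.mean_n2()))])
    for attempt in range(3):
        grid = np.arange(max(center - half_width, step),
                         min(center + half_width, 1.0 - step) + 1e-9, step)
        sweep = ensemble_sweep(spec, grid, generations=[generation],
                               n_realizations=n_realizations,
                               seed=seed + 1 + attempt, control="p")
        mean_n2 = sweep.mean_n2()
        i = int(np.argmax(mean_n2))
        if 0 < i < len(grid) - 1:
            return pseudo_critical_point(spec, generation, grid, sweep=sweep)
        center = float(grid[i])
    raise ValueError("second-largest-cluster peak kept hitting the window edge")


def fit_power_scaling(sizes: Sequence[float], values: Sequence[float]) -> ScalingFit:
    """Least-squares slope of log(value) against log(N).

    Returns the decay exponent as a positive number for decaying values
    (value ∝ N^(-exponent)) with its standard error.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 sizes")
    if np.any(values <= 0):
        raise ValueError("values must be positive for a log-log fit")
    x, y = np.log(sizes), np.log(values)
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = coef[0]
    dof = len(x) - 2
    if dof > 0 and res.size:
        s2 = res[0] / dof
        se = float(np.sqrt(s2 / np.sum((x - x.mean()) ** 2)))
    else:
        se = float("nan")
    return ScalingFit(sizes=sizes, values=values, exponent=float(-slope),
                      exponent_se=se, residual=float(res[0]) if res.size else 0.0,
                      fit_window=(int(sizes.min()), int(sizes.max())))


def fit_offset_scaling(
    sizes: Sequence[float],
    values: Sequence[float],
    eps_grid: np.ndarray | None = None,
    constrain: bool = True,
) -> ScalingFit:
    """Fit value(N) = c0 + a * N^(-eps) by grid search over eps with a
    linear least-squares subproblem for (c0, a) at each eps.

    Avoids the initialization sensitivity of a joint nonlinear fit; used for
    the discontinuous-transition extrapolation where c0 is the
    infinite-size order-parameter jump.

    With ``constrain=True`` (default) the extrapolated offset is required
    to be physically admissible for a nonnegative observable decaying
    toward its limit: 0 <= c0 <= min(values).  Without it, small-eps grid
    points (a nearly collinear design over a narrow size window) can win
    the residual race with wildly extrapolated offsets.
    """
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(sizes) < 4:
        raise ValueError("need at least 4 sizes for the offset fit")
    if eps_grid is None:
        eps_grid = np.arange(0.005, 1.0, 0.001)
    upper = float(values.min())
    best = None
    for eps in eps_grid:
        x = sizes ** (-eps)
        A = np.column_stack([np.ones_like(sizes), x])
        coef, res, rank, _ = np.linalg.lstsq(A, values, rcond=None)
        if rank < 2:
            continue
        if constrain and not 0.0 <= coef[0] <= upper:
            # best admissible fit at this eps lies on the c0 boundary
            for c0_b in (0.0, upper):
                a_b = float(x @ (values - c0_b) / (x @ x))
                sse_b = float(np.sum((c0_b + a_b * x - values) ** 2))
                if best is None or sse_b < best[0]:
                    best = (sse_b, float(eps), c0_b, a_b)
            continue
        sse = float(res[0]) if res.size else float(np.sum((A @ coef - values) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(eps), float(coef[0]), float(coef[1]))
    if best is None:
        raise ValueError("degenerate offset fit: design matrix rank-deficient")
    sse, eps, c0, a = best
    return ScalingFit(sizes=sizes, values=values, exponent=eps, exponent_se=float("nan"),
                      offset=c0, amplitude=a, residual=sse,
                      fit_window=(int(sizes.min()), int(sizes.max())))


def cluster_size_distribution(
    traces, generation: int, base: float = 1.3
) -> np.ndarray:
    """Pooled, logarithmically binned cluster-size distribution p_s at one
    generation, normalized per node: rows (s_geometric_mean, p_s).

    ``traces`` is an iterable of GenerationTrace with histograms kept.
    """
    pooled: dict[int, int] = {}
    n_traces = 0
    n_nodes_total = 0
    for trace in traces:
        n_traces += 1
        hist = trace.histograms[min(generation, len(trace.histograms)) - 1]
        total = sum(s * c for s, c in hist.items())
        n_nodes_total += total
        for s, c in hist.items():
            pooled[s] = pooled.get(s, 0) + c
    if n_traces == 0:
        raise ValueError("need at least one trace")
    smax = max(pooled)
    edges = [1.0]
    while edges[-1] <= smax:
        edges.append(max(edges[-1] * base, edges[-1] + 1))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ss = [s for s in pooled if lo <= s < hi]
        if not ss:
            continue
        count = sum(pooled[s] for s in ss)
        width = len(range(int(np.ceil(lo)), int(np.ceil(hi))))
        geo = float(np.exp(np.mean([np.log(s) for s in ss])))
        rows.append((geo, count / n_nodes_total / max(width, 1)))
    return np.array(rows)
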