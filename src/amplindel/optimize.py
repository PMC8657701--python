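"""Black-box optimization of the five pipeline parameters.

The objective is the read-processing chain run end to end on wild-type
samples, scored as the negative count of reads matched to the reference
amplicon database; minimizing it maximizes usable signal.  The optimizer
is sequential model-based: a Gaussian-process surrogate (Matern 5/2) with
expected-improvement acquisition over the bounded box, with a seeded
pure-random-search fallback.  Integer-valued knobs (maxdiffs, minampsize)
are explored on the real line and floored at evaluation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .readproc import (DenoiseParams, FilterParams, MergeParams, SearchParams,
                       run_chain)

log = logging.getLogger(__name__)

__all__ = ["ParamSpace", "OptResult", "PipelineObjective", "bayes_optimize"]

# published search intervals for the five tunables; the search step lists
# the two candidate identities (0.99 global / 1.0 exact), explored here as
# a narrow continuous bound
DEFAULT_BOUNDS = {
    "maxdiffs": (5.0, 82.0),
    "maxdiffpct": (2.0, 30.0),
    "maxee": (0.25, 1.5),
    "minampsize": (2.0, 30.0),
    "identity": (0.9, 1.0),
}
INTEGER_PARAMS = frozenset({"maxdiffs", "minampsize"})


@dataclass(frozen=True)
class ParamSpace:
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    integer: frozenset = INTEGER_PARAMS

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"{name}: need low < high, got ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def clip(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        return np.clip(x, lo, hi)

    def to_params(self, x) -> dict:
        return dict(zip(self.names, map(float, x)))


@dataclass
class OptResult:
    best_params: dict
    best_score: float
    trace: list  # (iteration, params dict, score)

    def convergence(self) -> list[float]:
        best, out = math.inf, []
        for _, _, s in self.trace:
            best = min(best, s)
            out.append(best)
        return out


class PipelineObjective:
    """Negative matched-read count of the chain on a fixed sample set.

    wt_only restricts the evaluation to samples flagged wild type in an
    optional metadata mapping (line_id -> is_wt), mirroring the practice of
    tuning on unedited material only.
    """

    def __init__(self, samples, db, wt_flags: dict | None = None,
                 wt_only: bool = True, min_overlap: int = 16):
        if wt_only and wt_flags is not None:
            samples = [s for s in samples if wt_flags.get(s[0], False)]
        self.samples = list(samples)
        if not self.samples:
            raise ValueError("no samples to optimize on")
        self.db = db
        self.min_overlap = min_overlap

    def __call__(self, params: dict) -> float:
        try:
            result = run_chain(
                self.samples,
                merge_params=MergeParams(maxdiffs=params["maxdiffs"],
                                         maxdiffpct=params["maxdiffpct"],
                                         min_overlap=self.min_overlap),
                filter_params=FilterParams(maxee=params["maxee"]),
                denoise_params=DenoiseParams(minampsize=params["minampsize"]),
                search_params=SearchParams(identity=params["identity"]),
                match_db=self.db,
                match_params=SearchParams(identity=params["identity"]),
            )
        except ValueError as exc:
            log.warning("objective failed at %s: %s", params, exc)
            return 0.0        # worst possible: nothing matched
        return -float(result.stats.get("matched_reads", 0))


def _expected_improvement(gp, x, f_best: float) -> np.ndarray:
    mu, sd = gp.predict(x, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (f_best - mu) / sd
    return (f_best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def bayes_optimize(space: ParamSpace, objective, budget: int = 50,
                   seed: int = 0, method: str = "gp",
                   n_initial: int | None = None) -> OptResult:
    """Sequential model-based minimization over a bounded box.

    method="gp" fits a Gaussian-process surrogate after n_initial random
    points and picks each next point by expected improvement (maximized
    over a seeded candidate cloud); method="random" is plain random
    search.  Identical seeds give identical traces.  budget must be at
    least dim + 2.
    """
    dim = len(space.names)
    if budget < dim + 2:
        raise ValueError(f"budget {budget} too small for {dim} dimensions")
    if method not in ("gp", "random"):
        raise ValueError("method must be 'gp' or 'random'")
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in space.bounds.values()])
    hi = np.array([b[1] for b in space.bounds.values()])
    span = hi - lo

    def sample(n):
        return lo + rng.random((n, dim)) * span

    if n_initial is None:
        n_initial = max(5, dim + 1) if method == "gp" else budget
    n_initial = min(n_initial, budget)

    xs, ys, trace = [], [], []

    def evaluate(x):
        params = space.to_params(x)
        y = float(objective(params))
        xs.append(np.asarray(x, dtype=float))
        ys.append(y)
        trace.append((len(trace), params, y))

    for x in sample(n_initial):
        evaluate(x)

    while len(trace) < budget:
        if method == "random":
            evaluate(sample(1)[0])
            continue
        xn = (np.array(xs) - lo) / span
        kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(dim, 0.3),
                                              nu=2.5)
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                      normalize_y=True,
                                      n_restarts_optimizer=1,
                                      random_state=int(rng.integers(2 ** 31)))
        gp.fit(xn, np.array(ys))
        cand = rng.random((1024, dim))
        # densify around the incumbent to allow local refinement
        inc = xn[int(np.argmin(ys))]
        local = np.clip(inc + rng.normal(0, 0.05, (256, dim)), 0, 1)
        cand = np.vstack([cand, local])
        ei = _expected_improvement(gp, cand, min(ys))
        x = lo + cand[int(np.argmax(ei))] * span
        evaluate(space.clip(x))

    best = int(np.argmin(ys))
    return OptResult(best_params=space.to_params(xs[best]),
                     best_score=ys[best], trace=trace)
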