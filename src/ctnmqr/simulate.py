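"""Synthetic low-Tucker-rank data, missing masks, RSE, and benchmark grids.

The generator draws a core and per-mode factors with i.i.d. standard-normal
entries and multiplies them out, which yields a tensor of exactly the
requested Tucker rank almost surely.  Masks remove entries uniformly at
random with an *exact* observed count M = round((1-mr) * prod(I_n)), so the
printed missing rate is met to within one entry (independent Bernoulli
sampling would only meet it in expectation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .solver import SolverConfig, complete
from .tensor_core import ShapeError, frobenius_norm, multi_mode_product

__all__ = [
    "ObservationMask",
    "BenchmarkRecord",
    "generate_tucker_tensor",
    "sample_mask",
    "rse",
    "run_benchmark",
    "records_to_frame",
    "write_benchmark",
]


@dataclass(frozen=True)
class ObservationMask:
    """Boolean tensor marking the observed index set Omega."""

    observed: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.observed)
        if obs.dtype != bool:
            raise TypeError("observed must be a boolean array")
        object.__setattr__(self, "observed", obs)

    @property
    def count(self) -> int:
        """Number M of observed entries."""
        return int(self.observed.sum())

    @property
    def missing_rate(self) -> float:
        """Achieved missing rate 1 - M / prod(I_n)."""
        return 1.0 - self.count / self.observed.size


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark grid cell: mean RSE/iterations over seeded replicates."""

    shape: tuple
    rank: tuple
    mr: float
    replicates: int
    mean_rse: float
    mean_iterations: float
    seed_base: int
    rses: tuple = ()
    iteration_counts: tuple = ()
    seeds: tuple = ()
    failures: int = 0


def generate_tucker_tensor(shape, rank, seed) -> np.ndarray:
    """Draw an exact low-Tucker-rank tensor.

    Core (R_1 x ... x R_N) and factors (I_i x R_i) have i.i.d. standard
    normal entries; the result C x_1 U_1 ... x_N U_N has Tucker rank
    (R_1, ..., R_N) almost surely.  ``seed`` may be an int or a Generator.
    """
    shape = tuple(int(s) for s in shape)
    rank = tuple(int(r) for r in rank)
    if len(rank) != len(shape):
        raise ShapeError("rank and shape must have the same length")
    for r, d in zip(rank, shape):
        if r > d:
            raise ValueError(f"rank {r} exceeds dimension {d}")
    rng = np.random.default_rng(seed)
    core = rng.standard_normal(rank)
    factors = [rng.standard_normal((d, r)) for d, r in zip(shape, rank)]
    return multi_mode_product(core, factors)


def sample_mask(shape, mr: float, seed) -> ObservationMask:
    """Uniform missing mask with exactly M = round((1-mr) * prod(I_n)) observed.

    Observed positions are sampled uniformly at random without replacement.
    """
    if not 0.0 <= mr < 1.0:
        raise ValueError(f"missing rate must lie in [0, 1), got {mr}")
    shape = tuple(int(s) for s in shape)
    total = int(np.prod(shape, dtype=np.int64))
    m = int(round((1.0 - mr) * total))
    rng = np.random.default_rng(seed)
    flat = np.zeros(total, dtype=bool)
    flat[rng.permutation(total)[:m]] = True
    return ObservationMask(observed=flat.reshape(shape))


def rse(x: np.ndarray, t: np.ndarray) -> float:
    """Relative squared error ||X - T||_F / ||T||_F."""
    x = np.asarray(x)
    t = np.asarray(t)
    if x.shape != t.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {t.shape}")
    denom = frobenius_norm(t)
    if denom == 0.0:
        raise ValueError("reference tensor has zero norm; RSE undefined")
    return frobenius_norm(x - t) / denom


def run_benchmark(grid, replicates: int, config: SolverConfig, seed_base: int) -> list:
    """Run the synthetic benchmark protocol over a grid of cells.

    Each cell is ``(shape, rank, mr)``.  Per replicate r a fresh tensor and
    mask are drawn with seed ``seed_base + r`` (distinct substreams for
    tensor, mask and solver initialization), the solver is run at the cell's
    rank with per-mode weights alpha_i = 1/N, and RSE and iteration count
    are recorded.  A replicate that fails numerically is counted in
    ``failures`` and excluded from the means; the run continues.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    records = []
    for shape, rank, mr in grid:
        shape = tuple(int(s) for s in shape)
        rank = tuple(int(r) for r in rank)
        cfg = replace(config, rank=rank, alpha=None, seed=config.seed)
        rses, iters, seeds = [], [], []
        failures = 0
        for r in range(replicates):
            seed = int(seed_base) + r
            seeds.append(seed)
            truth = generate_tucker_tensor(shape, rank, np.random.default_rng([seed, 1]))
            mask = sample_mask(shape, mr, np.random.default_rng([seed, 2]))
            try:
                res = complete(truth, mask.observed, replace(cfg, seed=seed))
            except ArithmeticError:
                failures += 1
                rses.append(float("nan"))
                iters.append(-1)
                continue
            rses.append(rse(res.completed, truth))
            iters.append(res.iterations)
        ok_rse = [v for v in rses if np.isfinite(v)]
        ok_it = [i for i in iters if i >= 0]
        records.append(
            BenchmarkRecord(
                shape=shape,
                rank=rank,
                mr=float(mr),
                replicates=replicates,
                mean_rse=float(np.mean(ok_rse)) if ok_rse else float("nan"),
                mean_iterations=float(np.mean(ok_it)) if ok_it else float("nan"),
                seed_base=int(seed_base),
                rses=tuple(rses),
                iteration_counts=tuple(iters),
                seeds=tuple(seeds),
                failures=failures,
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tidy one-row-per-cell table of benchmark results."""
    return pd.DataFrame(
        {
            "shape": ["x".join(map(str, r.shape)) for r in records],
            "rank": ["x".join(map(str, r.rank)) for r in records],
            "mr": [r.mr for r in records],
            "replicates": [r.replicates for r in records],
            "mean_rse": [r.mean_rse for r in records],
            "mean_iterations": [r.mean_iterations for r in records],
            "seed_base": [r.seed_base for r in records],
            "failures": [r.failures for r in records],
        }
    )


def write_benchmark(records, csv_path=None, json_path=None) -> None:
    """Write a benchmark: CSV summary (one row per cell) and/or JSON detail
    (per-replicate RSEs, iteration counts and seeds)."""
    if csv_path is not None:
        records_to_frame(records).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = [
            {
                "shape": list(r.shape),
                "rank": list(r.rank),
                "mr": r.mr,
                "replicates": r.replicates,
                "mean_rse": r.mean_rse,
                "mean_iterations": r.mean_iterations,
                "seed_base": r.seed_base,
                "rses": list(r.rses),
                "iteration_counts": list(r.iteration_counts),
                "seeds": list(r.seeds),
                "failures": r.failures,
            }
            for r in records
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
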