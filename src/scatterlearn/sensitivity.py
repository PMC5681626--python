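"""Variance-based global sensitivity analysis (Sobol indices).

For a model ``y = f(x₁, …, x_k)`` with independent inputs, the *main*
index ``S_i = V(E(Y|X_i)) / V(Y)`` measures the first-order (additive)
effect of input i, and the *total* index
``S_Ti = E(V(Y|X_~i)) / V(Y)`` additionally counts every interaction
involving input i, so ``0 ≤ S_i ≤ S_Ti ≤ 1`` up to Monte Carlo error.

Indices are estimated with the Saltelli pick-freeze scheme on a scrambled
Sobol sequence: the Saltelli-2010 estimator for main indices and the
Jansen estimator for totals (both standard low-variance choices), at a
cost of n(k+2) model evaluations for n base samples and k inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .doe import DesignSpace

__all__ = ["SobolIndices", "saltelli_matrices", "sobol_indices"]


@dataclass
class SobolIndices:
    """Main and total Sobol indices, one row per input per output.

    ``main`` and ``total`` have shape (k inputs, u outputs).  Estimates may
    fall slightly outside [0, 1] by quasi-Monte-Carlo error; they are
    reported as-is and flagged, never clipped.
    """

    main: np.ndarray
    total: np.ndarray
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    n_samples: int
    output_variance: np.ndarray

    @property
    def out_of_range(self) -> bool:
        """True when any estimate strays outside [0, 1] (MC noise)."""
        return bool(
            np.any(self.main < 0)
            or np.any(self.total > 1)
            or np.any(self.main > self.total)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, out in enumerate(self.output_names):
            for i, inp in enumerate(self.input_names):
                rows.append(
                    {
                        "output": out,
                        "input": inp,
                        "S_main": self.main[i, j],
                        "S_total": self.total[i, j],
                        "n": self.n_samples,
                    }
                )
        return pd.DataFrame(rows)


def saltelli_matrices(
    n: int, space: DesignSpace | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pick-freeze sample matrices A, B and A_B^(i) over the design space.

    A and B are independent blocks of a scrambled Sobol sequence; A_B^(i)
    equals A with column i replaced by B's.  Together they support index
    estimation from n(k+2) model evaluations.  ``n`` should preferably be a
    power of two (Sobol balance).
    """
    if n < 1:
        raise ValueError("base sample count must be positive")
    space = space or DesignSpace()
    k = 3
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(n)
    A = space.scale(base[:, :k])
    B = space.scale(base[:, k:])
    AB = []
    for i in range(k):
        M = A.copy()
        M[:, i] = B[:, i]
        AB.append(M)
    return A, B, AB


def sobol_indices(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    space: DesignSpace | None = None,
    n: int = 4096,
    seed: int | None = None,
    input_names: tuple[str, ...] = ("g", "sl_mm", "t_um"),
    output_names: tuple[str, ...] | None = None,
) -> SobolIndices:
    """Estimate main and total Sobol indices of a deterministic model.

    ``predict_fn`` maps an (m, 3) array of inputs in (g, sl_mm, t_um) order
    to an (m,) or (m, u) array of outputs — typically a fitted GP posterior
    mean.  Inputs are treated as independent uniforms over ``space``,
    matching the uniform space-filling treatment of the training design.
    """
    space = space or DesignSpace()
    A, B, AB = saltelli_matrices(n, space, seed)
    fA = np.atleast_2d(np.asarray(predict_fn(A), dtype=float).T).T
    fB = np.atleast_2d(np.asarray(predict_fn(B), dtype=float).T).T
    if fA.ndim == 1:
        fA, fB = fA[:, None], fB[:, None]
    u = fA.shape[1]
    fAB = np.stack(
        [np.atleast_2d(np.asarray(predict_fn(M), dtype=float).T).T.reshape(n, u)
         for M in AB]
    )  # (k, n, u)

    allf = np.concatenate([fA, fB], axis=0)
    V = allf.var(axis=0, ddof=1)  # (u,)
    if np.any(V <= 0):
        raise ValueError("degenerate output: zero variance, indices undefined")

    k = len(AB)
    main = np.empty((k, u))
    total = np.empty((k, u))
    for i in range(k):
        # Saltelli 2010 main-effect estimator
        main[i] = np.mean(fB * (fAB[i] - fA), axis=0) / V
        # Jansen total-effect estimator
        total[i] = 0.5 * np.mean((fA - fAB[i]) ** 2, axis=0) / V

    if output_names is None:
        output_names = tuple(f"y{j}" for j in range(u))
    return SobolIndices(
        main=main,
        total=total,
        input_names=input_names,
        output_names=output_names,
        n_samples=n,
        output_variance=V,
    )
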