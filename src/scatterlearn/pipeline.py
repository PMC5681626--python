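"""End-to-end orchestration of the computational experiments.

Chains the stages design → simulate → featurize → fit → invert and emits
the three evaluation studies:

* **convergence study** — forward-model test error (scaled RMSE of p and σ)
  versus training-set size, for single- and multi-response GP models on
  nested Sobol prefixes;
* **recovery study** — inverse estimation of (g, s_l) for held-out samples
  using their true thickness; reports scaled RMSE, maximum scaled error,
  mean signed errors (bias) and the Spearman correlation between the g and
  s_l errors;
* **thickness-perturbation study** — the recovery study rerun with the
  thickness deliberately misreported by ±10%, quantifying how thickness
  measurement error propagates into the estimates.

Everything is reproducible bit-for-bit from a single master seed:
per-image seeds are spawned from it with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doe import Design, DesignSpace, generate_design
from .features import characterize
from .gp import GPModel, fit_gp, scaled_rmse
from .inverse import InverseProblem, estimate_parameters
from .simulator import OpticsConfig, SampleParams, render_pattern

log = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "EvaluationReport",
    "spawn_seeds",
    "build_training_set",
    "fit_forward_model",
    "convergence_study",
    "recovery_study",
    "thickness_perturbation_study",
    "run_experiment",
]

FEATURE_COLUMNS = ("t_um", "g", "sl_mm", "p", "sigma", "nugget", "seed")


@dataclass
class TrainingSet:
    """Design points with their simulated pattern features."""

    design: Design
    features: pd.DataFrame      # one row per retained design point
    sim_config: OpticsConfig
    seeds: tuple[int, ...]      # per-point RNG seeds (distinct)
    dropped: tuple[int, ...] = ()  # design indices excluded (zero-power)

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, index) -> pd.DataFrame:
        return self.features.iloc[index]

    def inputs(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        """(n, 3) input array in (g, sl_mm, t_um) column order."""
        f = self.features if frame is None else frame
        return f[["g", "sl_mm", "t_um"]].to_numpy()

    def responses(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        f = self.features if frame is None else frame
        return f[["p", "sigma"]].to_numpy()


@dataclass
class EvaluationReport:
    """Aggregated study results; fields not produced by a study are None."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary, indent=1, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def spawn_seeds(base_seed: int, n: int) -> tuple[int, ...]:
    """Derive n distinct per-task seeds from one master seed (all < 2³¹)."""
    ss = np.random.SeedSequence(base_seed)
    return tuple(
        int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)
    )


def build_training_set(
    design: Design,
    optics: OpticsConfig | None = None,
    base_seed: int = 0,
) -> TrainingSet:
    """Simulate every design point and compress each image to (p, σ).

    Rows whose image collects no photons (possible at extreme settings or
    very low photon budgets) are excluded with a logged reason rather than
    propagated as undefined features.
    """
    optics = optics or OpticsConfig()
    seeds = spawn_seeds(base_seed, len(design))
    rows, dropped = [], []
    for i, (sample, seed) in enumerate(zip(design.points, seeds)):
        image = render_pattern(sample, optics, seed=seed)
        if image.total <= 0:
            log.warning(
                "design point %d %s produced a zero-power image; dropped",
                i, sample,
            )
            dropped.append(i)
            continue
        feats = characterize(image)
        rows.append(
            {
                "t_um": sample.t,
                "g": sample.g,
                "sl_mm": sample.s_l / 1000.0,
                "p": feats.p,
                "sigma": feats.sigma,
                "nugget": feats.nugget_1d,
                "seed": seed,
            }
        )
    features = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return TrainingSet(
        design=design,
        features=features,
        sim_config=optics,
        seeds=seeds,
        dropped=tuple(dropped),
    )


def fit_forward_model(
    training: TrainingSet,
    mode: str = "multi",
    n_train: int | None = None,
    log_responses: bool = True,
) -> GPModel:
    """Fit the forward map [g, s_l, t] → [p, σ] on the first n_train rows.

    Both responses are strictly positive and span orders of magnitude over
    the design box (transmission decays exponentially with optical
    thickness), so the GP is fitted to their logarithms by default and
    predictions are mapped back to the original scale.
    """
    frame = training.features if n_train is None else training.features.iloc[:n_train]
    space = training.design.space
    return fit_gp(
        training.inputs(frame),
        training.responses(frame),
        mode=mode,
        x_bounds=(space.lower, space.upper),
        response_names=("p", "sigma"),
        log_responses=log_responses,
    )


def convergence_study(
    training: TrainingSet,
    train_sizes: Sequence[int] = (50, 100, 150),
    n_test: int = 50,
) -> EvaluationReport:
    """Forward-model error versus training size for SRGP and MRGP models.

    The test set is the trailing ``n_test`` rows (a space-filling Sobol
    block disjoint from every training prefix); errors are scaled RMSEs of
    p and σ over that fixed set, in percent.
    """
    if max(train_sizes) + n_test > len(training):
        raise ValueError("training set too small for requested partition")
    test = training.features.iloc[len(training) - n_test:]
    X_test = training.inputs(test)
    Y_test = training.responses(test)

    rows = []
    for size in sorted(train_sizes):
        for mode in ("single", "multi"):
            model = fit_forward_model(training, mode=mode, n_train=size)
            pred = model.predict(X_test).mean
            for j, output in enumerate(("p", "sigma")):
                rows.append(
                    {
                        "train_size": size,
                        "mode": mode,
                        "output": output,
                        "scaled_rmse_pct": 100.0
                        * scaled_rmse(Y_test[:, j], pred[:, j]),
                    }
                )
    table = pd.DataFrame(rows)
    largest = table[table.train_size == max(train_sizes)]
    summary = {
        "n_test": int(n_test),
        "train_sizes": [int(s) for s in sorted(train_sizes)],
        "final_errors_pct": {
            f"e_{r.output}_{r.mode}": r.scaled_rmse_pct
            for r in largest.itertuples()
        },
    }
    return EvaluationReport(table=table, summary=summary)


def _recover(
    model: GPModel,
    test: pd.DataFrame,
    space: DesignSpace,
    thickness_factor: float = 1.0,
) -> pd.DataFrame:
    rows = []
    for r in test.itertuples():
        problem = InverseProblem(
            t_e=thickness_factor * r.t_um,
            p_e=r.p,
            sigma_e=r.sigma,
            model=model,
            space=space,
        )
        est = estimate_parameters(problem)
        rows.append(
            {
                "t_um": r.t_um,
                "g": r.g,
                "sl_mm": r.sl_mm,
                "g_hat": est.g_hat,
                "sl_hat_mm": est.sl_hat_mm,
                "F_min": est.F_min,
                "locus_flag": est.locus_flag,
            }
        )
    out = pd.DataFrame(rows)
    out["g_err"] = out.g - out.g_hat
    out["sl_err_mm"] = out.sl_mm - out.sl_hat_mm
    out["g_err_scaled"] = out.g_err / out.g
    out["sl_err_scaled"] = out.sl_err_mm / out.sl_mm
    return out


def _recovery_summary(table: pd.DataFrame) -> dict:
    n = len(table)
    rho = stats.spearmanr(table.g_err, table.sl_err_mm).statistic
    rho_t_g = stats.spearmanr(table.t_um, table.g_err_scaled.abs()).statistic
    rho_t_sl = stats.spearmanr(table.t_um, table.sl_err_scaled.abs()).statistic
    return {
        "N": int(n),
        "e_g_pct": 100.0 * scaled_rmse(table.g, table.g_hat),
        "e_sl_pct": 100.0 * scaled_rmse(table.sl_mm, table.sl_hat_mm),
        "max_g_err_pct": 100.0 * table.g_err_scaled.abs().max(),
        "max_sl_err_pct": 100.0 * table.sl_err_scaled.abs().max(),
        "mean_signed_g_err_pct": 100.0 * table.g_err_scaled.mean(),
        "mean_signed_sl_err_pct": 100.0 * table.sl_err_scaled.mean(),
        "se_g_err_pct": 100.0 * table.g_err_scaled.std(ddof=1) / np.sqrt(n),
        "se_sl_err_pct": 100.0 * table.sl_err_scaled.std(ddof=1) / np.sqrt(n),
        "spearman_rho": float(rho),
        "spearman_abs_err_vs_t": {"g": float(rho_t_g), "sl": float(rho_t_sl)},
    }


def recovery_study(model: GPModel, test: pd.DataFrame | TrainingSet,
                   space: DesignSpace | None = None) -> EvaluationReport:
    """Invert the forward model for each held-out sample at its true t.

    Each test point's measured (p, σ) and true thickness are fed to the
    bounded multistart optimizer; errors are reported relative to the true
    (g, s_l) that generated the pattern.
    """
    if isinstance(test, TrainingSet):
        space = space or test.design.space
        test = test.features
    space = space or DesignSpace()
    table = _recover(model, test, space, thickness_factor=1.0)
    return EvaluationReport(table=table, summary=_recovery_summary(table))


def thickness_perturbation_study(
    model: GPModel,
    test: pd.DataFrame | TrainingSet,
    factor: float,
    space: DesignSpace | None = None,
) -> EvaluationReport:
    """Recovery with the thickness misreported by ``factor`` (0.9 or 1.1)."""
    if isinstance(test, TrainingSet):
        space = space or test.design.space
        test = test.features
    space = space or DesignSpace()
    table = _recover(model, test, space, thickness_factor=factor)
    summary = _recovery_summary(table)
    summary["thickness_factor"] = float(factor)
    return EvaluationReport(table=table, summary=summary)


def run_experiment(
    n_points: int = 200,
    n_train: int = 150,
    n_test: int = 50,
    train_sizes: Sequence[int] | None = None,
    n_photons: int = 200_000,
    master_seed: int = 0,
    space: DesignSpace | None = None,
    optics: OpticsConfig | None = None,
    out_dir: str | Path | None = None,
    perturbation_factors: Sequence[float] = (0.9, 1.1),
) -> dict:
    """Run the full computational experiment and return all reports.

    Defaults are desk-scale: a 200-point Sobol design split 150/50 with
    2×10⁵ photons per image.  The full-scale configuration of the original
    study (400 points split 300/100, convergence increments of 50) is a
    matter of passing larger numbers.
    """
    if n_train + n_test > n_points:
        raise ValueError("n_train + n_test must not exceed n_points")
    space = space or DesignSpace()
    optics = optics or OpticsConfig(n_photons=n_photons)
    if train_sizes is None:
        train_sizes = [s for s in range(50, n_train + 1, 50)] or [n_train]

    log.info("simulating %d design points at %d photons each",
             n_points, optics.n_photons)
    design = generate_design(n_points, space)
    training = build_training_set(design, optics, base_seed=master_seed)

    log.info("convergence study at sizes %s", list(train_sizes))
    convergence = convergence_study(training, train_sizes, n_test)

    model = fit_forward_model(training, mode="multi", n_train=n_train)
    test = training.features.iloc[len(training) - n_test:]

    log.info("recovery study on %d held-out points", n_test)
    recovery = recovery_study(model, test, space)
    perturbed = {
        f: thickness_perturbation_study(model, test, f, space)
        for f in perturbation_factors
    }

    results = {
        "training": training,
        "model": model,
        "convergence": convergence,
        "recovery": recovery,
        "perturbed": perturbed,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        training.features.to_csv(out_dir / "features.csv", index=False)
        model.to_json(out_dir / "model.json")
        convergence.to_csv(out_dir / "convergence.csv")
        recovery.to_csv(out_dir / "recovery.csv")
        summary = {
            "master_seed": int(master_seed),
            "n_points": int(n_points),
            "n_photons": int(optics.n_photons),
            "convergence": convergence.summary,
            "recovery": recovery.summary,
            "perturbed": {str(f): r.summary for f, r in perturbed.items()},
        }
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, default=float)
        )
    return results
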