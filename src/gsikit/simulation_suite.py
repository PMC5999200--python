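"""Simulation-based evaluation of a stock-identification baseline.

Three standard designs quantify how well a baseline resolves its
reporting units:

* **100% simulations** — every simulated mixture is composed entirely
  of one reporting unit; the unit's estimated proportion measures how
  much of it is credited back, and individual assignments measure
  accuracy and efficiency at a posterior threshold.
* **Equal-proportion mixtures** — each reporting unit contributes the
  same number of fish; estimates are compared against the flat truth.
* **Dirichlet mixtures** — per replicate, true proportions are drawn
  from a symmetric Dirichlet (concentration 1.5 by default), covering a
  realistic range of stock compositions.

Simulated fish are drawn per locus from the source collection's
Dirichlet posterior predictive (a Polya urn on counts plus prior mass):
the two gene copies are drawn sequentially, the second conditioned on
the first.  Crucially, the drawn copies are *not* added to the baseline
counts when the fish is subsequently assigned — the leave-one-out
discipline that prevents the optimism of evaluating a fish against a
baseline containing its own gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import BaselineCollection
from .gsi_core import (
    FreqModel,
    McmcConfig,
    _result_from_logl,
    allele_counts,
    bootstrap_correct,
    loglik_matrix,
    posterior_freqs,
)

__all__ = [
    "SimulationDesign",
    "AccuracyReport",
    "MixtureTruth",
    "simulate_individual",
    "simulate_genotypes",
    "run_100pct",
    "run_equal",
    "run_dirichlet",
    "score_assignments",
]


@dataclass
class SimulationDesign:
    """One evaluation regime: kind, replicate count, size, Dirichlet alpha."""

    kind: str  # "pct100" | "equal" | "dirichlet"
    n_sims: int = 50
    mixture_size: int = 100
    alpha: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("pct100", "equal", "dirichlet"):
            raise ValueError("kind must be 'pct100', 'equal' or 'dirichlet'")
        if self.n_sims < 1 or self.mixture_size < 1:
            raise ValueError("n_sims and mixture_size must be >= 1")
        if self.kind == "dirichlet":
            if self.alpha is None:
                self.alpha = 1.5
            if self.alpha <= 0:
                raise ValueError("alpha must be > 0 for the dirichlet design")


@dataclass
class AccuracyReport:
    """Per-reporting-unit accuracy/efficiency at a posterior threshold.

    accuracy_r  = correctly assigned to r / total assigned to r
    efficiency_r = correctly assigned to r / truly belonging to r
    retained_r  = assigned anywhere / truly belonging to r
    Units with nobody assigned to them report accuracy as NaN.
    """

    table: pd.DataFrame
    threshold: float
    overall_accuracy: float
    overall_efficiency: float
    overall_retained: float
    overall_correct: float  # correctly assigned / all fish (unassigned count as wrong)


@dataclass
class MixtureTruth:
    """True proportions per reporting unit plus each fish's origin."""

    true_props: pd.Series
    origin_unit: list[str]
    origin_collection: list[str]


# ---------------------------------------------------------------------------
# posterior-predictive genotype simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(
    origins: np.ndarray, model: FreqModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n, L, 2) allele codes from each origin's posterior predictive.

    Copy 1 follows the predictive (x+lam)/(n+A*lam) — identical to the
    posterior-mean frequencies — and copy 2 duplicates copy 1 with
    probability 1/(n + A*lam + 1), otherwise it is a fresh predictive
    draw (the closed form of the sequential Polya-urn update).
    """
    enc = model.sample_genotypes(origins, rng)  # both copies iid predictive
    A = np.array([t.shape[1] for t in model.theta], dtype=float)
    urn_mass = model.n[origins] + A[None, :] * model.lam[None, :]  # (n, L)
    dup = rng.random(urn_mass.shape) < 1.0 / (urn_mass + 1.0)
    enc[:, :, 1] = np.where(dup, enc[:, :, 0], enc[:, :, 1])
    return enc


def simulate_individual(
    collection: str, model: FreqModel, rng: np.random.Generator
) -> np.ndarray:
    """One simulated fish from ``collection``; (L, 2) allele codes."""
    c = model.collections.index(collection)
    return simulate_genotypes(np.array([c]), model, rng)[0]


def _unit_collections(baseline: BaselineCollection) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {u: [] for u in baseline.reporting_units}
    for k, c in enumerate(baseline.collections):
        out[baseline.ru_map[c]].append(k)
    return out


def _origins_from_unit_counts(
    unit_counts: dict[str, int],
    baseline: BaselineCollection,
    rng: np.random.Generator,
    weights: str = "equal",
) -> tuple[np.ndarray, list[str]]:
    """Expand per-unit fish counts into collection origins.

    Within a multi-collection unit, fish are drawn from member
    collections with equal weight by default, or proportionally to
    sample size with ``weights="size"``.
    """
    ucols = _unit_collections(baseline)
    sizes = baseline.collection_sizes()
    origins, units = [], []
    for u, k in unit_counts.items():
        cols = ucols[u]
        if not cols:
            raise ValueError(f"reporting unit {u!r} has no collections")
        if weights == "size":
            w = np.array([sizes[baseline.collections[c]] for c in cols], dtype=float)
            w /= w.sum()
        else:
            w = np.full(len(cols), 1.0 / len(cols))
        origins.extend(rng.choice(cols, size=k, p=w))
        units.extend([u] * k)
    origins = np.array(origins, dtype=int)
    perm = rng.permutation(origins.size)
    return origins[perm], [units[i] for i in perm]


def _prepare(baseline: BaselineCollection, lam_policy="per_allele") -> FreqModel:
    return posterior_freqs(allele_counts(baseline), lam_policy)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_assignments(
    ru_posteriors: pd.DataFrame, truth: list[str], threshold: float = 0.70
) -> AccuracyReport:
    """Threshold-based assignment scoring against known origins.

    A fish is assigned to its highest-posterior reporting unit iff that
    posterior meets the threshold; otherwise it stays unassigned.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    units = list(ru_posteriors.columns)
    post = ru_posteriors.to_numpy()
    top = post.argmax(axis=1)
    assigned = post[np.arange(post.shape[0]), top] >= threshold
    truth = list(truth)
    rows = []
    for r, u in enumerate(units):
        truly = np.array([t == u for t in truth])
        to_u = assigned & (top == r)
        correct = int((to_u & truly).sum())
        n_to_u = int(to_u.sum())
        n_truly = int(truly.sum())
        rows.append(
            {
                "unit": u,
                "n_true": n_truly,
                "n_assigned_to": n_to_u,
                "n_correct": correct,
                "accuracy": correct / n_to_u if n_to_u else np.nan,
                "efficiency": correct / n_truly if n_truly else np.nan,
                "retained_fraction": float(assigned[truly].mean()) if n_truly else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("unit")
    truth_arr = np.array(truth)
    correct_all = assigned & (np.array([units[t] for t in top]) == truth_arr)

    def _nanmean(col) -> float:  # all-NaN (nobody assigned) is a valid NaN, not a warning
        vals = table[col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    return AccuracyReport(
        table=table,
        threshold=threshold,
        overall_accuracy=_nanmean("accuracy"),
        overall_efficiency=_nanmean("efficiency"),
        overall_retained=float(assigned.mean()) if len(truth) else float("nan"),
        overall_correct=float(correct_all.mean()) if len(truth) else float("nan"),
    )


# ---------------------------------------------------------------------------
# the three designs
# ---------------------------------------------------------------------------

def run_100pct(
    baseline: BaselineCollection,
    design: SimulationDesign,
    cfg: McmcConfig | None = None,
    threshold: float = 0.70,
    weights: str = "equal",
) -> tuple[AccuracyReport, pd.DataFrame]:
    """Single-unit mixtures for every reporting unit.

    Returns the individual-level accuracy report (pooled over all
    simulations) and a per-unit table of the mean estimated mixture
    proportion credited to the true unit — the two quantities are
    reported separately because they answer different questions.
    """
    if design.kind != "pct100":
        raise ValueError("design.kind must be 'pct100'")
    cfg = cfg or McmcConfig()
    rng = np.random.default_rng(design.seed)
    model = _prepare(baseline)
    units = baseline.reporting_units
    all_ru_post, all_truth = [], []
    prop_rows = []
    for u in units:
        credited = []
        for _ in range(design.n_sims):
            origins, fish_units = _origins_from_unit_counts(
                {u: design.mixture_size}, baseline, rng, weights
            )
            enc = simulate_genotypes(origins, model, rng)
            logl = loglik_matrix(enc, model)
            res = _result_from_logl(
                logl, [f"{u}_{i}" for i in range(len(origins))], baseline, cfg, rng
            )
            credited.append(res.ru_pi_hat[u])
            all_ru_post.append(res.ru_posterior)
            all_truth.extend(fish_units)
        prop_rows.append({"unit": u, "mean_credited_proportion": float(np.mean(credited))})
    report = score_assignments(pd.concat(all_ru_post, axis=0), all_truth, threshold)
    return report, pd.DataFrame(prop_rows).set_index("unit")


def run_equal(
    baseline: BaselineCollection,
    design: SimulationDesign,
    cfg: McmcConfig | None = None,
    weights: str = "equal",
    correct: bool = False,
) -> pd.DataFrame:
    """Equal-proportion mixtures: ``mixture_size`` fish per reporting unit.

    Returns a tidy frame (replicate, unit, truth, estimate[, corrected]).
    """
    if design.kind != "equal":
        raise ValueError("design.kind must be 'equal'")
    cfg = cfg or McmcConfig()
    rng = np.random.default_rng(design.seed)
    model = _prepare(baseline)
    units = baseline.reporting_units
    truth = 1.0 / len(units)
    rows = []
    for rep in range(design.n_sims):
        origins, _ = _origins_from_unit_counts(
            {u: design.mixture_size for u in units}, baseline, rng, weights
        )
        enc = simulate_genotypes(origins, model, rng)
        logl = loglik_matrix(enc, model)
        res = _result_from_logl(
            logl, [f"m{i}" for i in range(len(origins))], baseline, cfg, rng
        )
        corrected = (
            bootstrap_correct(res, baseline, cfg, model=model, rng=rng) if correct else None
        )
        for u in units:
            row = {"replicate": rep, "unit": u, "truth": truth, "estimate": res.ru_pi_hat[u]}
            if corrected is not None:
                row["corrected"] = corrected[u]
            rows.append(row)
    return pd.DataFrame(rows)


def run_dirichlet(
    baseline: BaselineCollection,
    design: SimulationDesign,
    cfg: McmcConfig | None = None,
    weights: str = "equal",
    correct: bool = True,
) -> tuple[pd.DataFrame, list[MixtureTruth]]:
    """Random-composition mixtures with Dirichlet-distributed truths.

    Per replicate the true unit proportions are drawn from a symmetric
    Dirichlet(alpha), fish origins are multinomial, and the estimate is
    bootstrap-corrected by default.  Returns the tidy truth-vs-estimate
    table (the scatter behind calibration plots) and the truth records.
    """
    if design.kind != "dirichlet":
        raise ValueError("design.kind must be 'dirichlet'")
    cfg = cfg or McmcConfig()
    rng = np.random.default_rng(design.seed)
    model = _prepare(baseline)
    units = baseline.reporting_units
    R = len(units)
    rows, truths = [], []
    for rep in range(design.n_sims):
        props = rng.dirichlet(np.full(R, design.alpha))
        unit_counts = rng.multinomial(design.mixture_size, props)
        origins, fish_units = _origins_from_unit_counts(
            {u: int(k) for u, k in zip(units, unit_counts)}, baseline, rng, weights
        )
        enc = simulate_genotypes(origins, model, rng)
        logl = loglik_matrix(enc, model)
        res = _result_from_logl(
            logl, [f"m{i}" for i in range(len(origins))], baseline, cfg, rng
        )
        corrected = (
            bootstrap_correct(res, baseline, cfg, model=model, rng=rng)
            if correct and cfg.n_boot > 0
            else None
        )
        truths.append(
            MixtureTruth(
                true_props=pd.Series(props, index=units),
                origin_unit=fish_units,
                origin_collection=[model.collections[o] for o in origins],
            )
        )
        for j, u in enumerate(units):
            row = {
                "replicate": rep,
                "unit": u,
                "truth": props[j],
                "estimate": res.ru_pi_hat[u],
            }
            if corrected is not None:
                row["corrected"] = corrected[u]
            rows.append(row)
    return pd.DataFrame(rows), truths
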