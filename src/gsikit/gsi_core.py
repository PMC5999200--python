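"""Bayesian genetic stock identification engine.

The model is the conditional ("empirical Bayes") mixture formulation
standard in mixed-stock analysis.  Baseline allele frequencies for each
collection are summarized by their Dirichlet posterior means

    theta[c, l, a] = (x[c, l, a] + lambda_l) / (n[c, l] + A_l * lambda_l)

with per-allele prior mass ``lambda_l = 1/A_l`` by default, so every
allele observed anywhere (baseline or mixture) has nonzero frequency in
every collection.  A mixture individual's likelihood under collection
``c`` is the diploid Hardy-Weinberg product over its typed loci.
Mixing proportions ``pi`` get a flat Dirichlet prior and are sampled by
a Gibbs sweep alternating the latent origins ``z_i | pi`` and
``pi | z``.  A parametric bootstrap subtracts the average re-estimation
bias from the reporting-unit proportions.

Leave-one-out self-assignment evaluates each baseline individual
against a baseline from which its own two gene copies per locus have
been removed, eliminating the optimism of assigning a fish to a
baseline that contains it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import AlleleIndex, BaselineCollection, GenotypeTable, build_allele_index
from .popgen_stats import AlleleCountTable, allele_counts

__all__ = [
    "FreqModel",
    "McmcConfig",
    "GSIResult",
    "posterior_freqs",
    "genotype_loglik",
    "loglik_matrix",
    "self_assign_loo",
    "fit_mixture",
    "bootstrap_correct",
]

_LOG2 = np.log(2.0)


@dataclass
class McmcConfig:
    """Sampler settings: iterations, burn-in, bootstrap reps, seed."""

    n_iter: int = 20000
    burn_in: int = 1000
    n_boot: int = 100
    seed: int | None = None
    pi_prior: str = "flat"  # "flat" (alpha=1 per collection) or "one_over_c"

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        if self.pi_prior not in ("flat", "one_over_c"):
            raise ValueError("pi_prior must be 'flat' or 'one_over_c'")

    def pi_alpha(self, n_collections: int) -> np.ndarray:
        if self.pi_prior == "flat":
            return np.ones(n_collections)
        return np.full(n_collections, 1.0 / n_collections)


@dataclass
class FreqModel:
    """Dirichlet-posterior-mean allele frequencies per collection."""

    collections: list[str]
    loci: list[str]
    lam: np.ndarray  # per-locus prior mass per allele
    theta: list[np.ndarray]  # per locus, (C, A_l), rows sum to 1
    x: list[np.ndarray]  # raw counts, needed for leave-one-out decrements
    n: np.ndarray  # (C, L) gene copies
    index: AlleleIndex
    kept_locus_idx: list[int]  # positions of kept loci in the source index

    _cum: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_collections(self) -> int:
        return len(self.collections)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def cum_theta(self) -> np.ndarray:
        """(C, L, Amax) padded cumulative frequencies, for fast sampling."""
        if self._cum is None:
            amax = max((t.shape[1] for t in self.theta), default=0)
            cum = np.ones((self.n_collections, self.n_loci, amax))
            for l, t in enumerate(self.theta):
                cum[:, l, : t.shape[1]] = np.cumsum(t, axis=1)
                cum[:, l, t.shape[1] :] = 1.0
            self._cum = cum
        return self._cum

    def sample_genotypes(self, origins: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw (n, L, 2) allele codes under HWE from posterior-mean theta."""
        cum = self.cum_theta()[origins]  # (n, L, Amax)
        u = rng.random((origins.size, self.n_loci, 2))
        return (u[..., None] > cum[:, :, None, :]).sum(axis=-1).astype(np.int32)


def posterior_freqs(
    counts: AlleleCountTable, lam_policy: str | float = "per_allele"
) -> FreqModel:
    """Posterior-mean allele frequencies from counts.

    ``lam_policy`` is either ``"per_allele"`` (lambda_l = 1/A_l, unit
    total prior mass per locus) or a positive constant applied to every
    allele.  Loci with no observed alleles are dropped with a warning.
    """
    keep, dropped = [], []
    for l in range(counts.n_loci):
        (keep if counts.x[l].shape[1] > 0 else dropped).append(l)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} locus/loci with no observed alleles: "
            + ", ".join(counts.loci[l] for l in dropped)
        )
    lam = np.empty(len(keep))
    theta, x = [], []
    for k, l in enumerate(keep):
        A = counts.x[l].shape[1]
        if lam_policy == "per_allele":
            lam[k] = 1.0 / A
        else:
            lam[k] = float(lam_policy)
            if lam[k] <= 0:
                raise ValueError("constant lambda must be positive")
        th = (counts.x[l] + lam[k]) / (counts.n[:, l][:, None] + A * lam[k])
        theta.append(th)
        x.append(counts.x[l])
    return FreqModel(
        collections=list(counts.collections),
        loci=[counts.loci[l] for l in keep],
        lam=lam,
        theta=theta,
        x=x,
        n=counts.n[:, keep],
        index=counts.index,
        kept_locus_idx=keep,
    )


def _encode_for_model(table: GenotypeTable, model: FreqModel) -> np.ndarray:
    enc = model.index.encode(table)
    return enc[:, model.kept_locus_idx, :]


def loglik_matrix(enc: np.ndarray, model: FreqModel) -> np.ndarray:
    """(N, C) log-likelihood of each individual under each collection.

    ``enc`` is (N, L, 2) allele codes aligned to the model's kept loci;
    missing loci (code -1) contribute zero, so a fully untyped fish is
    equally likely under every collection.
    """
    N = enc.shape[0]
    out = np.zeros((N, model.n_collections))
    for l in range(model.n_loci):
        a, b = enc[:, l, 0], enc[:, l, 1]
        typed = np.where(a >= 0)[0]
        if typed.size == 0:
            continue
        th = model.theta[l]
        la = np.log(th[:, a[typed]])  # (C, k)
        lb = np.log(th[:, b[typed]])
        contrib = la + lb + np.where(a[typed] != b[typed], _LOG2, 0.0)
        out[typed, :] += contrib.T
    return out


def genotype_loglik(enc_indiv: np.ndarray, c: int, model: FreqModel) -> float:
    """Log-likelihood of one (L, 2)-encoded individual under collection c."""
    return float(loglik_matrix(enc_indiv[None, :, :], model)[0, c])


def loo_loglik(enc_indiv: np.ndarray, c: int, model: FreqModel) -> float:
    """Log-likelihood under collection ``c`` with the individual's own gene
    copies removed from the counts before forming theta (leave-one-out)."""
    total = 0.0
    for l in range(model.n_loci):
        a, b = int(enc_indiv[l, 0]), int(enc_indiv[l, 1])
        if a < 0:
            continue
        A = model.x[l].shape[1]
        lam = model.lam[l]
        xa = model.x[l][c, a] - 1.0
        xb = model.x[l][c, b] - (1.0 if a != b else 1.0)
        if a == b:
            xa = model.x[l][c, a] - 2.0
        n = model.n[c, l] - 2.0
        if min(xa, n) < 0 or (a != b and xb < 0):
            raise ValueError("leave-one-out decrement below zero: individual not in counts?")
        den = n + A * lam
        if a == b:
            ta = (xa + lam) / den
            total += 2.0 * np.log(ta)
        else:
            ta = (xa + lam) / den
            tb = (xb + lam) / den
            total += np.log(2.0 * ta * tb)
    return total


def _ru_aggregate(df: pd.DataFrame, baseline: BaselineCollection) -> pd.DataFrame:
    units = baseline.reporting_units
    out = pd.DataFrame(0.0, index=df.index, columns=units)
    for c in baseline.collections:
        out[baseline.ru_map[c]] += df[c]
    return out


def self_assign_loo(
    baseline: BaselineCollection,
    lam_policy: str | float = "per_allele",
    index: AlleleIndex | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out self-assignment posteriors.

    Each labeled baseline individual is scored against every collection;
    for its own collection the allele frequencies are recomputed with the
    individual's gene copies removed.  The posterior uses an equal prior
    across collections.  Returns (collection posteriors, reporting-unit
    posteriors) as individual-indexed DataFrames.
    """
    gt = baseline.genotypes
    counts = allele_counts(baseline, index)
    model = posterior_freqs(counts, lam_policy)
    enc = _encode_for_model(gt, model)
    logl = loglik_matrix(enc, model)
    col_of = {c: k for k, c in enumerate(baseline.collections)}
    for i in range(gt.n_individuals):
        c = col_of[gt.labels[i]]
        logl[i, c] = loo_loglik(enc[i], c, model)
    logl -= logl.max(axis=1, keepdims=True)
    post = np.exp(logl)
    post /= post.sum(axis=1, keepdims=True)
    post_df = pd.DataFrame(post, index=gt.individuals, columns=baseline.collections)
    return post_df, _ru_aggregate(post_df, baseline)


@dataclass
class GSIResult:
    """Mixture-model output: per-fish posteriors, traces, and summaries."""

    collections: list[str]
    reporting_units: list[str]
    posterior: pd.DataFrame  # individuals x collections, rows sum to 1
    ru_posterior: pd.DataFrame  # individuals x reporting units
    pi_trace: np.ndarray  # retained samples x collections
    pi_hat: pd.Series  # posterior mean per collection
    ru_pi_hat: pd.Series  # posterior mean per reporting unit
    ci: pd.DataFrame  # reporting unit x (low, high), central 95%
    pi_corrected: pd.Series | None = None  # bootstrap-corrected RU proportions

    def ru_trace(self, baseline: BaselineCollection) -> np.ndarray:
        units = self.reporting_units
        out = np.zeros((self.pi_trace.shape[0], len(units)))
        upos = {u: k for k, u in enumerate(units)}
        for j, c in enumerate(self.collections):
            out[:, upos[baseline.ru_map[c]]] += self.pi_trace[:, j]
        return out


def _gibbs_pi(
    lik: np.ndarray, alpha: np.ndarray, cfg: McmcConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs sampler for mixing proportions.

    ``lik`` is the (n, C) per-fish likelihood matrix scaled so each row's
    maximum is 1 (a per-row constant cancels in the origin probabilities).
    Returns (pi trace after burn-in, posterior mean origin probabilities).
    """
    n, C = lik.shape
    pi = np.full(C, 1.0 / C)
    n_keep = cfg.n_iter - cfg.burn_in
    trace = np.empty((n_keep, C))
    post_acc = np.zeros((n, C))
    for t in range(cfg.n_iter):
        w = lik * pi
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        z = (np.cumsum(w, axis=1) < u).sum(axis=1)
        cnt = np.bincount(z, minlength=C)
        pi = rng.dirichlet(alpha + cnt)
        if t >= cfg.burn_in:
            trace[t - cfg.burn_in] = pi
            post_acc += w
    return trace, post_acc / n_keep


def _fit_pi(
    logl: np.ndarray, cfg: McmcConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lik = np.exp(logl - logl.max(axis=1, keepdims=True))
    alpha = cfg.pi_alpha(logl.shape[1])
    return _gibbs_pi(lik, alpha, cfg, rng)


def fit_mixture(
    mixture: GenotypeTable,
    baseline: BaselineCollection,
    cfg: McmcConfig | None = None,
    lam_policy: str | float = "per_allele",
    run_bootstrap: bool = True,
    rng: np.random.Generator | None = None,
) -> GSIResult:
    """Estimate mixture composition by Gibbs sampling.

    The allele index is built on baseline plus mixture so mixture-private
    alleles are representable.  ``run_bootstrap`` applies the parametric
    bootstrap bias correction (``cfg.n_boot`` replicates) at the
    reporting-unit level.
    """
    if mixture.n_individuals == 0:
        raise ValueError("empty mixture")
    cfg = cfg or McmcConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    index = build_allele_index(baseline.genotypes, extra=mixture)
    counts = allele_counts(baseline, index)
    model = posterior_freqs(counts, lam_policy)
    enc = _encode_for_model(mixture, model)
    logl = loglik_matrix(enc, model)
    result = _result_from_logl(logl, mixture.individuals, baseline, cfg, rng)
    if run_bootstrap and cfg.n_boot > 0:
        result.pi_corrected = bootstrap_correct(result, baseline, cfg, model=model, rng=rng)
    return result


def _result_from_logl(
    logl: np.ndarray,
    individuals: list[str],
    baseline: BaselineCollection,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> GSIResult:
    trace, post = _fit_pi(logl, cfg, rng)
    post_df = pd.DataFrame(post, index=list(individuals), columns=baseline.collections)
    ru_post = _ru_aggregate(post_df, baseline)
    pi_hat = pd.Series(trace.mean(axis=0), index=baseline.collections)
    units = baseline.reporting_units
    ru_trace = np.zeros((trace.shape[0], len(units)))
    upos = {u: k for k, u in enumerate(units)}
    for j, c in enumerate(baseline.collections):
        ru_trace[:, upos[baseline.ru_map[c]]] += trace[:, j]
    ru_pi_hat = pd.Series(ru_trace.mean(axis=0), index=units)
    lo, hi = np.percentile(ru_trace, [2.5, 97.5], axis=0)
    ci = pd.DataFrame({"low": lo, "high": hi}, index=units)
    return GSIResult(
        collections=list(baseline.collections),
        reporting_units=units,
        posterior=post_df,
        ru_posterior=ru_post,
        pi_trace=trace,
        pi_hat=pi_hat,
        ru_pi_hat=ru_pi_hat,
        ci=ci,
    )


def bootstrap_correct(
    result: GSIResult,
    baseline: BaselineCollection,
    cfg: McmcConfig,
    model: FreqModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Parametric-bootstrap bias correction of reporting-unit proportions.

    For each of ``cfg.n_boot`` replicates, a mixture of the original size
    is simulated from the baseline's posterior-mean frequencies at the
    estimated collection proportions and re-estimated with the same
    sampler.  The mean re-estimation bias is subtracted from the raw
    reporting-unit estimate; negative corrected values are clamped to
    zero and the vector renormalized to sum to 1.
    """
    if cfg.n_boot == 0:
        return result.ru_pi_hat.copy()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = posterior_freqs(allele_counts(baseline))
    n = result.posterior.shape[0]
    C = len(result.collections)
    pi_c = result.pi_hat.to_numpy()
    pi_c = np.clip(pi_c, 0, None)
    pi_c = pi_c / pi_c.sum()
    units = result.reporting_units
    boot = np.zeros((cfg.n_boot, len(units)))
    boot_cfg = cfg
    for b in range(cfg.n_boot):
        origins = rng.choice(C, size=n, p=pi_c)
        enc = model.sample_genotypes(origins, rng)
        logl = loglik_matrix(enc, model)
        r = _result_from_logl(logl, [f"b{i}" for i in range(n)], baseline, boot_cfg, rng)
        boot[b] = r.ru_pi_hat.to_numpy()
    bias = boot.mean(axis=0) - result.ru_pi_hat.to_numpy()
    corrected = np.clip(result.ru_pi_hat.to_numpy() - bias, 0.0, None)
    s = corrected.sum()
    corrected = corrected / s if s > 0 else np.full(len(units), 1.0 / len(units))
    return pd.Series(corrected, index=units)
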