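"""High-level analysis stages behind the command-line interface.

Each function here is one stage of a stock-identification study:
baseline summary statistics, reporting-group proposal, simulation-based
evaluation, multiplex-subset accuracy, mixture estimation, and panel
QC.  They consume library objects, write plain-text artifacts under an
output directory, and record a JSON manifest (config, seed, versions,
input checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import BaselineCollection, GenotypeTable
from .gsi_core import McmcConfig, fit_mixture, self_assign_loo
from .panel_qc import QcThresholds, genotyping_error_rate, screen_loci
from .popgen_stats import (
    allele_counts,
    cse_chord_distance,
    heterozygosity,
    hwe_tests,
    nj_tree,
    pairwise_fst,
)
from .reporting_groups import misassignment_matrix, propose_merges
from .simulation_suite import SimulationDesign, run_100pct, run_dirichlet, run_equal, score_assignments

__all__ = [
    "baseline_summary",
    "propose_groups",
    "run_design",
    "subset_accuracy",
    "estimate_fishery",
    "panel_qc_report",
    "write_manifest",
]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, stage: str, config: dict, inputs: list | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in (inputs or []) if Path(p).is_file()},
        "versions": {
            "gsikit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def baseline_summary(
    baseline: BaselineCollection,
    outdir,
    n_perm: int = 10000,
    n_boot: int = 100,
    seed: int | None = None,
) -> dict:
    """Heterozygosity, HWE report, F_ST, allele counts, chord matrix, NJ tree.

    Writes labeled CSVs and a newick tree under ``outdir`` and returns
    the in-memory results keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = allele_counts(baseline)
    het = heterozygosity(counts)
    hwe = hwe_tests(baseline, n_perm=n_perm, seed=seed)
    fst, fst_locus = pairwise_fst(counts)
    chord = cse_chord_distance(counts)
    tree, newick = nj_tree(chord, counts=counts, n_boot=n_boot, seed=seed)

    pd.DataFrame(
        {
            "locus": counts.loci,
            "n_alleles": counts.index.n_alleles,
            "h_obs": het.h_o_per_locus,
            "h_exp": het.h_e_per_locus,
            "theta": fst_locus.to_numpy(),
        }
    ).to_csv(outdir / "per_locus_summary.csv", index=False)
    fst.to_csv(outdir / "pairwise_fst.csv")
    chord.to_csv(outdir / "chord_distance.csv")
    pd.DataFrame(hwe.p, index=hwe.collections, columns=hwe.loci).to_csv(outdir / "hwe_pvalues.csv")
    (outdir / "nj_tree.nwk").write_text(newick + "\n")
    summary = {
        "n_collections": counts.n_collections,
        "n_loci": counts.n_loci,
        "total_alleles": counts.index.total_alleles,
        "mean_alleles_per_locus": counts.index.mean_alleles_per_locus,
        "h_obs_overall": het.h_o_overall,
        "h_exp_overall": het.h_e_overall,
        "hwe_tests": hwe.n_tests,
        "hwe_significant_raw": hwe.n_significant_raw,
        "hwe_significant_bonferroni": hwe.n_significant_bonferroni,
        "fst_mean": float(np.nanmean(fst.to_numpy()[np.triu_indices(len(fst), 1)])),
        "fst_min": float(np.nanmin(fst.to_numpy()[np.triu_indices(len(fst), 1)])),
        "fst_max": float(np.nanmax(fst.to_numpy()[np.triu_indices(len(fst), 1)])),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {
        "counts": counts,
        "het": het,
        "hwe": hwe,
        "fst": fst,
        "fst_per_locus": fst_locus,
        "chord": chord,
        "tree": tree,
        "newick": newick,
        "summary": summary,
    }


def propose_groups(
    baseline: BaselineCollection,
    outdir,
    min_n: int = 30,
    mutual_cutoff: float = 0.20,
    n_boot: int = 100,
    seed: int | None = None,
) -> dict:
    """Leave-one-out mis-assignments + NJ tree -> merge proposal and ru_map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    post, _ru_post = self_assign_loo(baseline)
    mis = misassignment_matrix(post, baseline.genotypes.labels)
    counts = allele_counts(baseline)
    chord = cse_chord_distance(counts)
    tree, newick = nj_tree(chord, counts=counts, n_boot=n_boot, seed=seed)
    proposal = propose_merges(
        tree, mis, sizes=baseline.collection_sizes(), min_n=min_n, mutual_cutoff=mutual_cutoff
    )
    from .reporting_groups import apply_ru_map

    merged = apply_ru_map(baseline, proposal.unions)
    mis.to_csv(outdir / "misassignment_matrix.csv")
    (outdir / "nj_tree.nwk").write_text(newick + "\n")
    (outdir / "merge_proposal.json").write_text(
        json.dumps(proposal.as_records(), indent=2) + "\n"
    )
    pd.DataFrame(
        {"collection": merged.collections, "repunit": [merged.ru_map[c] for c in merged.collections]}
    ).to_csv(outdir / "ru_map.csv", index=False)
    return {"misassignment": mis, "proposal": proposal, "baseline": merged, "tree": tree}


def run_design(
    baseline: BaselineCollection,
    design: SimulationDesign,
    outdir,
    cfg: McmcConfig | None = None,
    threshold: float = 0.70,
) -> dict:
    """Dispatch one of the three evaluation designs and write tidy CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or McmcConfig()
    if design.kind == "pct100":
        report, credited = run_100pct(baseline, design, cfg, threshold=threshold)
        report.table.to_csv(outdir / "accuracy_report.csv")
        credited.to_csv(outdir / "credited_proportions.csv")
        return {"report": report, "credited": credited}
    if design.kind == "equal":
        df = run_equal(baseline, design, cfg)
        df.to_csv(outdir / "equal_design.csv", index=False)
        return {"estimates": df}
    df, truths = run_dirichlet(baseline, design, cfg)
    df.to_csv(outdir / "dirichlet_design.csv", index=False)
    return {"estimates": df, "truths": truths}


def subset_accuracy(
    baseline: BaselineCollection,
    multiplex_map: dict[str, str],
    design: SimulationDesign,
    cfg: McmcConfig | None = None,
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Assignment accuracy as multiplexes of loci are added cumulatively.

    Every multiplex is first evaluated alone with 100% simulations; the
    best one seeds the cumulative series and the rest join in descending
    order of standalone accuracy.  Returns one row per cumulative subset
    with its locus count and mean accuracy/efficiency.
    """
    loci = baseline.genotypes.loci
    missing = [l for l in loci if l not in multiplex_map]
    if missing:
        raise ValueError(f"multiplex_map does not cover loci: {', '.join(missing[:5])} ...")
    groups: dict[str, list[str]] = {}
    for l in loci:
        groups.setdefault(multiplex_map[l], []).append(l)
    for name, ls in groups.items():
        if not ls:
            raise ValueError(f"multiplex {name!r} has no loci")
    cfg = cfg or McmcConfig()

    def _accuracy(subset: list[str], seed_offset: int) -> tuple[float, float, float]:
        sub_gt = baseline.genotypes.subset_loci(subset)
        sub_base = BaselineCollection(sub_gt, list(baseline.collections), dict(baseline.ru_map))
        d = SimulationDesign(
            kind="pct100",
            n_sims=design.n_sims,
            mixture_size=design.mixture_size,
            seed=None if design.seed is None else design.seed + seed_offset,
        )
        report, _ = run_100pct(sub_base, d, cfg, threshold=threshold)
        return report.overall_accuracy, report.overall_efficiency, report.overall_correct

    alone = {}
    for k, (name, ls) in enumerate(sorted(groups.items())):
        alone[name] = _accuracy(ls, 1000 + k)
    order = sorted(alone, key=lambda m: (-alone[m][2], m))
    rows = []
    cumulative: list[str] = []
    for k, name in enumerate(order):
        cumulative = cumulative + groups[name]
        acc, eff, correct = _accuracy(cumulative, 2000 + k) if k > 0 else alone[name]
        rows.append(
            {
                "subset": " + ".join(order[: k + 1]),
                "n_multiplexes": k + 1,
                "n_loci": len(cumulative),
                "accuracy": acc,
                "efficiency": eff,
                "prop_correct": correct,
            }
        )
    return pd.DataFrame(rows)


def estimate_fishery(
    baseline: BaselineCollection,
    mixtures: dict[str, GenotypeTable],
    outdir,
    cfg: McmcConfig | None = None,
) -> dict:
    """Mixture composition per fishery sample, with CIs and corrections.

    Empty mixture tables are skipped with a warning entry.  Writes per-
    sample CSVs (per-unit proportions and per-fish top assignments) plus
    a stacked composition table across samples.
    """
    import warnings

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or McmcConfig()
    results = {}
    stacked = []
    for name, mix in mixtures.items():
        if mix.n_individuals == 0:
            warnings.warn(f"mixture {name!r} is empty; skipped")
            continue
        res = fit_mixture(mix, baseline, cfg)
        results[name] = res
        props = pd.DataFrame(
            {
                "raw": res.ru_pi_hat,
                "ci_low": res.ci["low"],
                "ci_high": res.ci["high"],
                "corrected": res.pi_corrected
                if res.pi_corrected is not None
                else res.ru_pi_hat,
            }
        )
        props.index.name = "repunit"
        props.to_csv(outdir / f"{name}_proportions.csv")
        top_unit = res.ru_posterior.idxmax(axis=1)
        top_post = res.ru_posterior.max(axis=1)
        pd.DataFrame({"top_unit": top_unit, "posterior": top_post}).to_csv(
            outdir / f"{name}_assignments.csv"
        )
        for u in res.reporting_units:
            stacked.append(
                {
                    "sample": name,
                    "repunit": u,
                    "n": mix.n_individuals,
                    "proportion": float(props.loc[u, "corrected"]),
                }
            )
    pd.DataFrame(stacked).to_csv(outdir / "composition_stacked.csv", index=False)
    return results


def panel_qc_report(
    genotypes: GenotypeTable,
    outdir,
    depth: pd.DataFrame | None = None,
    pairs: list[tuple[str, str]] | None = None,
    thresholds: QcThresholds | None = None,
    seed: int | None = None,
) -> dict:
    """Locus screen plus duplicate-based error estimate; writes CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = screen_loci(genotypes, depth=depth, thresholds=thresholds, seed=seed)
    report.table.to_csv(outdir / "locus_qc.csv")
    out = {"qc": report}
    if pairs:
        err = genotyping_error_rate(genotypes, pairs)
        err.per_locus.to_csv(outdir / "error_per_locus.csv")
        (outdir / "error_rate.json").write_text(
            json.dumps(
                {
                    "error_rate": err.error_rate,
                    "error_rate_pct": err.error_rate_pct,
                    "discordant_count": err.discordant_count,
                    "comparisons": err.comparisons,
                },
                indent=2,
            )
            + "\n"
        )
        out["error"] = err
    return out
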