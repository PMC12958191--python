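"""The core-reduction study: nested cores, group classification, statistics.

One replicate simulates a population, builds the pedigree and genomic
relationship machinery, computes (i) exact ssGBLUP reliabilities from the
inverse of the mixed-model coefficient matrix and (ii) approximated
reliabilities through the APY block-sparse path for a benchmark core (sized
by the eigenvalue threshold) and a schedule of nested smaller cores.
Genotyped animals are classified per comparison into R-core (retained in
the reduced core), F-core (formerly core, dropped by the reduction) and
N-core (never core), and each reduced scenario is compared with the
benchmark by mean difference, Pearson correlation, and the intercept/slope
of the regression of benchmark reliabilities on the reduced-core ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla

from . import simulate as sim_mod
from .approx import (
    ApproxResult,
    effective_record_weights,
    genomic_reliabilities,
    propagate_to_pedigree,
)
from .config import RunConfig
from .evaluation import (
    ModelParams,
    ReliabilityTable,
    assemble_mme,
    build_H_inverse,
    exact_reliabilities,
)
from .relationships import (
    build_A22,
    build_A_inverse,
    build_apy_inverse,
    build_grm,
    choose_core_size,
    select_nested_cores,
)
from .simulate import Pedigree, PhenotypeSet

__all__ = [
    "GroupLabels",
    "ComparisonStats",
    "ExperimentReport",
    "classify_groups",
    "compare_reliabilities",
    "noncore_core_ratio",
    "stratify_by_progeny",
    "run_core_reduction_experiment",
]

logger = logging.getLogger(__name__)

GROUPS = ("R_core", "F_core", "N_core")
DEFAULT_PROGENY_BINS = ((0, 0), (1, 2), (3, 10), (11, None))


@dataclass
class GroupLabels:
    """Per-genotyped-animal group for one (benchmark, reduced) core pair."""

    labels: pd.Series  # values in GROUPS

    def ids_in(self, group: str) -> np.ndarray:
        return self.labels.index[self.labels == group].to_numpy()


@dataclass
class ComparisonStats:
    """Benchmark-vs-candidate agreement statistics for one animal group."""

    group: str
    n_animals: int
    MD: Optional[float]
    correlation: Optional[float]
    intercept: Optional[float]
    slope: Optional[float]
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n_animals,
            "MD": self.MD,
            "correlation": self.correlation,
            "intercept": self.intercept,
            "slope": self.slope,
            "undefined": self.undefined,
        }


@dataclass
class ExperimentReport:
    """Tables produced by one core-reduction study.

    ``stats`` has one row per replicate x scenario x group x comparison
    ("benchmark_approx" mirrors the complete-data analysis: approximated
    benchmark vs reduced cores; "exact" mirrors the reduced-data analysis:
    exact MME reliabilities vs each core's approximation).
    """

    stats: pd.DataFrame
    fidelity: pd.DataFrame
    ratios: pd.DataFrame
    strata: pd.DataFrame
    core_sizes: dict
    eigen_threshold: float
    seeds: list
    config_echo: dict
    failed_replicates: dict = field(default_factory=dict)
    alternative: Optional["ExperimentReport"] = None


def classify_groups(benchmark_core, reduced_core, genotyped_ids) -> GroupLabels:
    """R-core = reduced core; F-core = benchmark \\ reduced; N-core = rest."""
    bench = set(np.asarray(benchmark_core).tolist())
    red = set(np.asarray(reduced_core).tolist())
    if not red:
        raise ValueError("reduced core must contain at least one animal")
    if not red <= bench:
        raise ValueError("reduced core is not nested in the benchmark core")
    genotyped_ids = np.asarray(genotyped_ids)
    if not bench <= set(genotyped_ids.tolist()):
        raise ValueError("benchmark core contains non-genotyped animals")
    lab = np.where(
        np.isin(genotyped_ids, list(red)),
        "R_core",
        np.where(np.isin(genotyped_ids, list(bench)), "F_core", "N_core"),
    )
    return GroupLabels(labels=pd.Series(lab, index=genotyped_ids))


def compare_reliabilities(
    benchmark: ReliabilityTable,
    candidate: ReliabilityTable,
    labels: GroupLabels,
) -> list[ComparisonStats]:
    """Per-group MD, Pearson r and OLS of benchmark (response) on candidate.

    MD = mean(benchmark - candidate), so a candidate that underestimates
    reliability yields MD > 0.  Groups with fewer than 2 animals or zero
    candidate variance get MD only and are flagged undefined.
    """
    b = benchmark.series()
    c = candidate.series()
    out: list[ComparisonStats] = []
    for group in GROUPS:
        ids = labels.ids_in(group)
        if len(ids) == 0:
            out.append(ComparisonStats(group, 0, None, None, None, None, True))
            continue
        bb = b.reindex(ids)
        cc = c.reindex(ids)
        if bb.isna().any() or cc.isna().any():
            raise KeyError(f"reliability missing for animals in group {group}")
        bb = bb.to_numpy()
        cc = cc.to_numpy()
        md = float(np.mean(bb - cc))
        if len(ids) < 2 or np.var(cc) == 0.0 or np.var(bb) == 0.0:
            out.append(ComparisonStats(group, len(ids), md, None, None, None, True))
            continue
        slope = float(np.cov(cc, bb, ddof=1)[0, 1] / np.var(cc, ddof=1))
        intercept = float(np.mean(bb) - slope * np.mean(cc))
        r = float(np.corrcoef(cc, bb)[0, 1])
        out.append(ComparisonStats(group, len(ids), md, r, intercept, slope))
    return out


def noncore_core_ratio(n_genotyped: int, n_core: int) -> float:
    """(n_genotyped - n_core) / n_core — the noncore:core ratio."""
    if n_core < 1 or n_core > n_genotyped:
        raise ValueError("need 1 <= n_core <= n_genotyped")
    return (n_genotyped - n_core) / n_core


def stratify_by_progeny(
    deltas: pd.Series,
    pedigree: Pedigree,
    phenotypes: PhenotypeSet,
    bins: Sequence[tuple] = DEFAULT_PROGENY_BINS,
) -> pd.DataFrame:
    """Mean reliability difference by progeny-count bin and record status.

    ``bins`` are inclusive (lo, hi) progeny-count intervals (hi=None means
    unbounded).  Empty strata are reported with count 0 and no statistics.
    """
    prog = pedigree.progeny_counts().reindex(deltas.index)
    if prog.isna().any():
        raise KeyError("animals in deltas missing from pedigree")
    has_rec = deltas.index.isin(phenotypes.records.index)
    rows = []
    for lo, hi in bins:
        in_bin = (prog >= lo) & (prog <= (hi if hi is not None else np.inf))
        for flag in (False, True):
            mask = in_bin.to_numpy() & (has_rec == flag)
            sel = deltas[mask]
            rows.append(
                {
                    "progeny_bin": f"{lo}-{hi if hi is not None else 'inf'}",
                    "has_record": flag,
                    "n": int(mask.sum()),
                    "mean_MD": float(sel.mean()) if len(sel) else None,
                    "mean_abs_MD": float(sel.abs().mean()) if len(sel) else None,
                }
            )
    return pd.DataFrame(rows)


def _run_replicate(config: RunConfig, seed: int, h2: float) -> dict:
    sim = config.simulation.replace(seed=seed)
    ped = sim_mod.simulate_pedigree(sim)
    geno_all = sim_mod.simulate_genotypes(ped, sim)
    phen = sim_mod.simulate_phenotypes(ped, geno_all, sim)
    gids = sim_mod.select_genotyped(ped, sim)
    gset = geno_all.subset(gids)

    numrel = build_A_inverse(ped)
    A22 = build_A22(ped, gids)
    numrel.A22, numrel.A22_ids = A22, gids
    grm = build_grm(gset, A22, config.blend_alpha)
    params = ModelParams.from_heritability(h2, tau=config.tau, omega=config.omega)

    n_eig = choose_core_size(gset, config.cores.eigen_threshold)
    sizes = sorted(
        {max(1, int(round(f * n_eig))) for f in config.cores.schedule_fractions},
        reverse=True,
    )
    partitions = select_nested_cores(gids, sizes, seed=seed)

    # pedigree-only exact reliabilities (the conventional contribution)
    mme_ped = assemble_mme(phen, numrel.A_inverse, ped.ids, params)
    rel_ped = exact_reliabilities(mme_ped, params, numrel.inbreeding, "pedigree")

    # exact ssGBLUP reliabilities from the full MME (the benchmark truth)
    Ginv = sla.inv(grm.G)
    Hinv = build_H_inverse(numrel, Ginv, gids, params)
    mme_ss = assemble_mme(phen, Hinv, ped.ids, params)
    rel_exact = exact_reliabilities(mme_ss, params, numrel.inbreeding, "exact")

    weights = effective_record_weights(
        pd.Series(rel_ped.series().reindex(gids).to_numpy(), index=gids), A22, params
    )
    grm_diag = grm.diagonal()

    approx: dict[str, ApproxResult] = {}
    for part in partitions:
        apy = build_apy_inverse(grm, part)
        grel = genomic_reliabilities(
            apy, grm_diag, weights, params, sketch=config.sketch
        )
        approx[part.scenario_label] = propagate_to_pedigree(
            rel_ped,
            grel,
            params,
            mme_ped,
            numrel.inbreeding,
            scenario_label=part.scenario_label,
            used_sketch=config.sketch is not None,
        )
    return {
        "pedigree": ped,
        "phenotypes": phen,
        "genotyped_ids": gids,
        "partitions": partitions,
        "n_eigen_core": n_eig,
        "rel_pedigree": rel_ped,
        "rel_exact": rel_exact,
        "approx": approx,
    }


def run_core_reduction_experiment(config: RunConfig) -> ExperimentReport:
    """Run the full study over the configured replicate seeds."""
    h2 = config.analysis_h2
    seeds = config.replicate_seeds()
    stat_rows, fid_rows, ratio_rows, strata_frames = [], [], [], []
    core_sizes: dict = {}
    failed: dict = {}

    for rep, seed in enumerate(seeds):
        try:
            res = _run_replicate(config, seed, h2)
        except Exception as exc:  # a failed replicate is reported, not fatal
            logger.error("replicate %d (seed %d) failed: %s", rep, seed, exc)
            failed[rep] = str(exc)
            continue

        parts = res["partitions"]
        gids = res["genotyped_ids"]
        bench_part = parts[0]
        bench = res["approx"][bench_part.scenario_label]
        core_sizes[rep] = {
            "eigen_core": res["n_eigen_core"],
            "schedule": [p.n_core for p in parts],
        }

        exact_series = res["rel_exact"].series()
        fid_rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "correlation_all": float(
                    np.corrcoef(bench.final_reliability, exact_series)[0, 1]
                ),
                "correlation_genotyped": float(
                    np.corrcoef(
                        bench.final_reliability.reindex(gids),
                        exact_series.reindex(gids),
                    )[0, 1]
                ),
            }
        )

        for pos, part in enumerate(parts):
            ratio_rows.append(
                {
                    "replicate": rep,
                    "position": pos,
                    "scenario": part.scenario_label,
                    "n_core": part.n_core,
                    "n_noncore": part.n_noncore,
                    "ratio": noncore_core_ratio(len(gids), part.n_core),
                }
            )

        for pos, part in enumerate(parts[1:], start=1):
            labels = classify_groups(bench_part.core_ids, part.core_ids, gids)
            cand = res["approx"][part.scenario_label]
            for comparison, bench_table in (
                ("benchmark_approx", bench.table),
                ("exact", res["rel_exact"]),
            ):
                for st in compare_reliabilities(bench_table, cand.table, labels):
                    row = st.to_dict()
                    row.update(
                        replicate=rep, seed=seed, position=pos,
                        scenario=part.scenario_label, comparison=comparison,
                    )
                    stat_rows.append(row)

        # exact-vs-benchmark row (the reduced-data "25k vs 25k" analogue)
        labels_full = classify_groups(bench_part.core_ids, bench_part.core_ids, gids)
        for st in compare_reliabilities(res["rel_exact"], bench.table, labels_full):
            row = st.to_dict()
            row.update(
                replicate=rep, seed=seed, position=0,
                scenario=bench_part.scenario_label, comparison="exact",
            )
            stat_rows.append(row)

        smallest = res["approx"][parts[-1].scenario_label]
        deltas = (
            bench.final_reliability.reindex(gids)
            - smallest.final_reliability.reindex(gids)
        )
        sdf = stratify_by_progeny(deltas, res["pedigree"], res["phenotypes"])
        sdf.insert(0, "replicate", rep)
        strata_frames.append(sdf)

    report = ExperimentReport(
        stats=pd.DataFrame(stat_rows),
        fidelity=pd.DataFrame(fid_rows),
        ratios=pd.DataFrame(ratio_rows),
        strata=(
            pd.concat(strata_frames, ignore_index=True)
            if strata_frames
            else pd.DataFrame()
        ),
        core_sizes=core_sizes,
        eigen_threshold=config.cores.eigen_threshold,
        seeds=list(seeds),
        config_echo=config.to_dict(),
        failed_replicates=failed,
    )
    if config.h2_alternative is not None:
        alt = config.replace(heritability=config.h2_alternative, h2_alternative=None)
        report.alternative = run_core_reduction_experiment(alt)
    return report
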