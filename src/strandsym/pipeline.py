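"""Composable analysis workflows tying the modules into reproducible runs.

Three levels: per-genome profiling (indexes + distances across orders),
individual-genome assessment against a set of shuffled controls (t tests),
and group assessment of many genomes each paired with one control
(Wilcoxon). The CLI is a thin layer over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer_core import compile_tables, count_kmers
from .sequence_io import GenomeAssembly, make_control_set
from .symmetry_indexes import compute_indexes
from .symmetry_stats import (
    DEFAULT_ALPHA,
    ExtentDecision,
    IndividualTest,
    PairedGroupTest,
    determine_extent,
    individual_t_test,
    wilcoxon_signed_rank,
)
from .wsd_core import compute_wsd

__all__ = [
    "profile_assembly",
    "IndividualAnalysis",
    "analyze_individual",
    "GroupAnalysis",
    "analyze_group",
]

PROFILE_COLUMNS = [
    "k", "S1", "S2", "M", "WSD1", "nWSD1", "WSD2", "nWSD2",
    "max_ulam", "max_WSD2",
]


def profile_assembly(
    assembly: GenomeAssembly, k_min: int = 1, k_max: int = 8
) -> pd.DataFrame:
    """Per-order symmetry indexes and word symmetry distances for one genome.

    Records shorter than k contribute no windows at that order; orders at
    which no record is long enough are omitted.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    rows = []
    for k in range(k_min, k_max + 1):
        tables = [count_kmers(rec, k) for rec in assembly.records if len(rec) >= k]
        if not tables:
            continue
        table = compile_tables(tables)
        idx = compute_indexes(table)
        wsd = compute_wsd(table, keep_moves=False)
        rows.append(
            {
                "k": k,
                "S1": idx.s1,
                "S2": idx.s2,
                "M": idx.m_pairs,
                "WSD1": wsd.wsd1,
                "nWSD1": wsd.nwsd1,
                "WSD2": wsd.wsd2,
                "nWSD2": wsd.nwsd2,
                "max_ulam": wsd.max_ulam,
                "max_WSD2": wsd.max_wsd2,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


@dataclass
class IndividualAnalysis:
    genome_id: str
    genome_profile: pd.DataFrame
    control_profiles: list[pd.DataFrame]
    tests: list[IndividualTest] = field(default_factory=list)
    extent: ExtentDecision | None = None


def analyze_individual(
    genome: GenomeAssembly,
    k_min: int = 1,
    k_max: int = 8,
    n_controls: int = 30,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    metric: str = "WSD2",
) -> IndividualAnalysis:
    """One genome against ``n_controls`` shuffled controls.

    t tests and an extent decision are produced when ``n_controls >= 2``;
    with a single control only the descriptive profiles are reported.
    """
    gprof = profile_assembly(genome, k_min, k_max)
    controls = make_control_set(genome, n_controls, seed)
    cprofs = [profile_assembly(c, k_min, k_max) for c in controls.controls]
    result = IndividualAnalysis(
        genome_id=genome.genome_id, genome_profile=gprof, control_profiles=cprofs
    )
    if n_controls < 2:
        return result
    for k in range(max(2, k_min), k_max + 1):
        grow = gprof[gprof["k"] == k]
        if grow.empty:
            continue
        gval = float(grow[metric].iloc[0])
        cvals = [
            float(cp.loc[cp["k"] == k, metric].iloc[0])
            for cp in cprofs
            if not cp.loc[cp["k"] == k].empty
        ]
        if len(cvals) < 2:
            continue
        result.tests.append(individual_t_test(gval, cvals, k=k, alpha=alpha))
    if result.tests:
        result.extent = determine_extent(
            result.tests, alpha=alpha, k_max=max(t.k for t in result.tests),
            metric=metric,
        )
    return result


@dataclass
class GroupAnalysis:
    group_id: str
    n_genomes: int
    values: pd.DataFrame  # long: genome_id, role, k, metric columns
    tests: dict[str, list[PairedGroupTest]] = field(default_factory=dict)
    extents: dict[str, ExtentDecision] = field(default_factory=dict)


def analyze_group(
    genomes: list[GenomeAssembly],
    group_id: str = "all",
    k_min: int = 1,
    k_max: int = 8,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    metrics: tuple[str, ...] = ("WSD1", "nWSD1", "WSD2", "nWSD2", "S1", "S2"),
    extent_metric: str = "WSD2",
    min_group_size: int = 5,
) -> GroupAnalysis:
    """Paired genome-vs-control comparison for a group of genomes.

    Each genome is paired with exactly one shuffled control (substream seed
    ``seed + index``). Per order and metric a Wilcoxon signed-rank test is
    run; the extent decision uses ``extent_metric``.
    """
    if len(genomes) < min_group_size:
        raise ValueError(
            f"group {group_id!r} has {len(genomes)} genomes; need >= {min_group_size}"
        )
    frames = []
    for i, genome in enumerate(genomes):
        control = make_control_set(genome, 1, seed + i).controls[0]
        for role, asm in (("genomic", genome), ("control", control)):
            prof = profile_assembly(asm, k_min, k_max)
            prof.insert(0, "role", role)
            prof.insert(0, "genome_id", genome.genome_id)
            frames.append(prof)
    values = pd.concat(frames, ignore_index=True)
    analysis = GroupAnalysis(
        group_id=group_id, n_genomes=len(genomes), values=values
    )
    for metric in metrics:
        tests = []
        for k in range(max(2, k_min), k_max + 1):
            sub = values[values["k"] == k].pivot(
                index="genome_id", columns="role", values=metric
            )
            if sub.empty or sub.isna().any().any():
                continue
            tests.append(
                wilcoxon_signed_rank(
                    sub["genomic"].to_numpy(),
                    sub["control"].to_numpy(),
                    k=k,
                    metric=metric,
                    alpha=alpha,
                )
            )
        analysis.tests[metric] = tests
    extent_tests = analysis.tests.get(extent_metric, [])
    if extent_tests:
        analysis.extents[extent_metric] = determine_extent(
            extent_tests, alpha=alpha, k_max=max(t.k for t in extent_tests),
            metric=extent_metric,
        )
    return analysis
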