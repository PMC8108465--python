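"""Molecular design breeding: multi-locus haplotype grouping, group-wise
trait comparison, two-locus epistasis tables, and optimal-combination
selection.

Works on inbred panels, so only homozygous genotype combinations define
haplotype groups; heterozygous or missing samples at any grouping locus
are excluded (and counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

logger = logging.getLogger("hybridforge")


@dataclass
class HaplotypeGroup:
    loci: list[str]
    combo: tuple  # homozygous dosage (0.0 or 2.0) per locus
    members: list[str]
    label: str


def haplotype_groups(
    gm: GenotypeMatrix, loci: list[str]
) -> tuple[list[HaplotypeGroup], list[str]]:
    """Partition homozygous samples by their genotype combo at ``loci``.

    Returns (groups, excluded sample ids). Groups get canonical labels
    Hap1..HapK in lexicographic order of the dosage combo (all-reference
    first), so label numbers are reproducible but arbitrary.
    """
    vidx = gm.variant_index()
    missing = [l for l in loci if l not in vidx]
    if missing:
        raise KeyError(f"loci absent from genotype matrix: {missing}")
    cols = gm.dosages[:, [vidx[l] for l in loci]]
    homo = np.isin(cols, (0.0, 2.0)).all(axis=1)
    excluded = [s for s, ok in zip(gm.sample_ids, homo) if not ok]
    combos: dict[tuple, list[str]] = {}
    for s, row, ok in zip(gm.sample_ids, cols, homo):
        if ok:
            combos.setdefault(tuple(row), []).append(s)
    if not combos:
        raise ValueError("no sample is homozygous at all loci")
    groups = [
        HaplotypeGroup(list(loci), combo, members, f"Hap{k + 1}")
        for k, (combo, members) in enumerate(sorted(combos.items()))
    ]
    logger.info(
        "haplotype grouping over %d loci: %d groups, %d samples excluded",
        len(loci), len(groups), len(excluded),
    )
    return groups, excluded


@dataclass
class GroupStats:
    """Per group x trait summaries and Welch-test p-values vs a reference."""

    reference: str
    table: pd.DataFrame  # group, trait, n, mean, sd, p_vs_ref


def group_trait_stats(
    groups: list[HaplotypeGroup],
    phenotypes: pd.DataFrame,
    reference: str,
    min_size: int = 2,
) -> GroupStats:
    """Mean/sd/n per group and trait plus Welch two-sample p vs reference.

    ``phenotypes`` is indexed by sample id with one column per trait.
    Groups with fewer than ``min_size`` phenotyped members are excluded
    and logged. Degenerate variance in both groups yields p = 1 with a
    warning.
    """
    by_label = {g.label: g for g in groups}
    if reference not in by_label:
        raise KeyError(f"reference group {reference!r} not found")
    ref_members = [s for s in by_label[reference].members if s in phenotypes.index]
    if not ref_members:
        raise ValueError("reference group has no phenotyped members")
    rows = []
    for g in groups:
        members = [s for s in g.members if s in phenotypes.index]
        if len(members) < min_size:
            logger.info("group %s below min size (%d); excluded", g.label, len(members))
            continue
        for trait in phenotypes.columns:
            vals = phenotypes.loc[members, trait].to_numpy(dtype=float)
            ref_vals = phenotypes.loc[ref_members, trait].to_numpy(dtype=float)
            if g.label == reference:
                p = 1.0
            elif np.var(vals) == 0.0 and np.var(ref_vals) == 0.0:
                p = 1.0 if np.mean(vals) == np.mean(ref_vals) else 0.0
                logger.warning(
                    "degenerate variances for %s/%s; p set to %g", g.label, trait, p
                )
            else:
                p = float(stats.ttest_ind(vals, ref_vals, equal_var=False).pvalue)
            rows.append(
                {
                    "group": g.label,
                    "trait": trait,
                    "n": len(members),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "p_vs_ref": p,
                }
            )
    return GroupStats(reference, pd.DataFrame(rows))


def two_locus_epistasis_table(
    gm: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    phenotype: pd.Series,
) -> tuple[pd.DataFrame, float, float]:
    """Genotype-combination cell means and the interaction contrast.

    Cells are the observed (dosage at A, dosage at B) combinations with
    n, mean and sd of the phenotype. The interaction contrast is the
    2x2 double difference over the homozygote corners,
    (AA,BB) - (AA,bb) - (aa,BB) + (aa,bb), with its standard error; an
    empty corner leaves the contrast NaN (flagged in the log).

    Returns (cell table, contrast, contrast se).
    """
    vidx = gm.variant_index()
    for l in (locus_a, locus_b):
        if l not in vidx:
            raise KeyError(f"locus {l!r} absent from genotype matrix")
    a = gm.dosages[:, vidx[locus_a]]
    b = gm.dosages[:, vidx[locus_b]]
    rows = []
    cells: dict[tuple, np.ndarray] = {}
    for da in np.unique(a[np.isfinite(a)]):
        for db in np.unique(b[np.isfinite(b)]):
            ids = [
                s
                for s, xa, xb in zip(gm.sample_ids, a, b)
                if xa == da and xb == db and s in phenotype.index
            ]
            if not ids:
                continue
            vals = phenotype.loc[ids].to_numpy(dtype=float)
            cells[(da, db)] = vals
            rows.append(
                {
                    "dosage_a": da,
                    "dosage_b": db,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    corners = [(2.0, 2.0), (2.0, 0.0), (0.0, 2.0), (0.0, 0.0)]
    signs = [1.0, -1.0, -1.0, 1.0]
    if any(c not in cells for c in corners):
        logger.warning("empty homozygote cell; interaction contrast undefined")
        return table, float("nan"), float("nan")
    contrast = sum(s * np.mean(cells[c]) for s, c in zip(signs, corners))
    se = np.sqrt(
        sum(np.var(cells[c], ddof=1) / len(cells[c]) for c in corners)
    )
    return table, float(contrast), float(se)


def select_optimal(
    stats_: GroupStats,
    minimize: list[str],
    protect: str | None = None,
    protect_p: float = 0.05,
    min_size: int = 2,
) -> pd.DataFrame:
    """Rank haplotype groups for breeding selection.

    Groups whose ``protect`` trait is *significantly reduced* relative
    to the reference (mean below the reference AND Welch p <
    ``protect_p``) are filtered out; survivors are ranked
    lexicographically by their means on the ``minimize`` traits
    (ascending), ties broken by group label. Returns the ranked table
    (empty, with a log message, when no group passes).
    """
    t = stats_.table
    wide_mean = t.pivot(index="group", columns="trait", values="mean")
    wide_p = t.pivot(index="group", columns="trait", values="p_vs_ref")
    wide_n = t.pivot(index="group", columns="trait", values="n")
    groups = [g for g in wide_mean.index if wide_n.loc[g].min() >= min_size]
    if protect is not None:
        ref_mean = wide_mean.loc[stats_.reference, protect]
        ok = []
        for g in groups:
            reduced = (
                wide_mean.loc[g, protect] < ref_mean
                and wide_p.loc[g, protect] < protect_p
            )
            if not reduced:
                ok.append(g)
        groups = ok
    if not groups:
        logger.warning("no haplotype group passes the selection constraints")
        return pd.DataFrame(columns=["group", "rank", *minimize])
    order = sorted(
        groups, key=lambda g: tuple(wide_mean.loc[g, m] for m in minimize) + (g,)
    )
    out = pd.DataFrame(
        {
            "group": order,
            "rank": np.arange(1, len(order) + 1),
            **{m: [wide_mean.loc[g, m] for g in order] for m in minimize},
        }
    )
    return out
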