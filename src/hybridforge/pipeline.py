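"""End-to-end analysis of a synthetic NC-II study bundle.

Glue over the stage modules: condense multi-environment phenotypes to
line BLUPs, derive mid-parent heterosis per cross, run the GWAS battery
(maternal panel, per-tester F1 populations, MPH), call QTLs per scan,
and classify the merged map into heterotic classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .design import cross_id
from .gwas import GWASResult, run_gwas_battery
from .pheno import compute_mph, fit_line_blup
from .qtl import QTL, call_qtls, classify_merged_map
from .simulate import StudyBundle

logger = logging.getLogger("hybridforge")


def line_blups(bundle: StudyBundle, trait: str) -> pd.Series:
    """BLUP every line (parents and hybrids) for one trait."""
    return fit_line_blup(bundle.traits, trait)


def mph_series(bundle: StudyBundle, blup: pd.Series) -> pd.Series:
    """Mid-parent heterosis per cross, indexed by cross id."""
    vals = {}
    for m, p in bundle.design.crosses:
        cid = cross_id(m, p)
        if cid in blup.index and m in blup.index and p in blup.index:
            vals[cid] = compute_mph(blup[cid], blup[m], blup[p])
    return pd.Series(vals)


def analyze_trait(
    bundle: StudyBundle,
    trait: str,
    cfg: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline for one trait of a study bundle.

    Returns (classified merged QTL map, dict of GWAS results keyed by
    (population, trait)).
    """
    cfg = cfg or AnalysisConfig()
    blup = line_blups(bundle, trait)
    mph = mph_series(bundle, blup)
    mph_name = f"MPH.{trait}"

    maternal = bundle.parents.subset_samples(bundle.design.maternal_ids)
    maternal_pheno = pd.DataFrame(
        {trait: blup.reindex(bundle.design.maternal_ids)}
    ).dropna()

    f1_pops: dict = {}
    f1_pheno: dict = {}
    for tester in bundle.design.paternal_ids:
        ids = [
            cross_id(m, p) for m, p in bundle.design.crosses if p == tester
        ]
        f1_pops[tester] = bundle.f1.subset_samples(ids)
        f1_pheno[tester] = pd.DataFrame(
            {trait: blup.reindex(ids), mph_name: mph.reindex(ids)}
        )

    results = run_gwas_battery(
        maternal, maternal_pheno, f1_pops, f1_pheno,
        traits=[trait], mph_traits=[mph_name],
    )

    maternal_qtls: list[QTL] = []
    f1_qtls: list[QTL] = []
    mph_qtls: list[QTL] = []
    for (pop, tr), res in results.items():
        ld = maternal if pop == "maternal" else f1_pops[pop]
        qtls = call_qtls(res, ld, cfg)
        if pop == "maternal":
            maternal_qtls.extend(qtls)
        elif tr == mph_name:
            mph_qtls.extend(qtls)
        else:
            f1_qtls.extend(qtls)

    classified = classify_merged_map(maternal_qtls, f1_qtls, mph_qtls)
    return classified, results


def recovered_classes(
    classified: pd.DataFrame, truth: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Match planted causal variants to classified merged QTL intervals.

    A truth row matches a merged QTL when its position falls inside the
    interval (same chromosome). Returns truth annotated with the
    recovered class label (or None)."""
    labels = []
    for row in truth[truth["trait"] == trait].itertuples():
        hit = classified[
            (classified["chrom"] == row.chrom)
            & (classified["start"] <= row.pos)
            & (classified["end"] >= row.pos)
        ]
        labels.append(hit["class"].iloc[0] if len(hit) else None)
    out = truth[truth["trait"] == trait].copy()
    out["recovered_class"] = labels
    return out
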