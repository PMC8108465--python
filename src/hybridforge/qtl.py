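"""QTL summarization from GWAS scans: grouping significant SNPs into
loci, LD-aware locus merging, peak extension, cross-population map
merging, and heterotic classification.

The caller follows a clumping recipe tuned to long-range LD in
multi-parent maize panels: significant SNPs (p <= 1e-6) closer than the
800-kbp LD decay length form seed loci; same-chromosome loci merge when
any cross-locus SNP pair has r^2 > 0.1 and the peaks sit within 5 Mbp,
iterated to a fixpoint; loci with >= 10 significant SNPs become QTLs,
smaller ones get one +/-400 kbp extension collecting suggestive SNPs
(p <= 1e-4) before the >= 10 rule is re-checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import GenotypeMatrix

logger = logging.getLogger("hybridforge")


@dataclass
class QTL:
    """A merged genomic interval (1-based, closed) with its peak SNP."""

    chrom: str
    start: int
    end: int
    peak_id: str
    peak_pos: int
    peak_p: float
    n_sig_snps: int
    support: str  # "significant" | "suggestive"
    population: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("peak SNP lies outside its QTL interval")
        if self.support not in ("significant", "suggestive"):
            raise ValueError(f"unknown support level {self.support!r}")

    def overlaps(self, other: "QTL") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def pairwise_r2(
    ld_source: GenotypeMatrix, variant_a: str, variant_b: str
) -> float:
    """LD between two variants: squared Pearson correlation of dosages.

    Samples missing either dosage are excluded pairwise. Monomorphic
    input (after exclusion) is undefined and treated as 0 with a flag in
    the log.
    """
    idx = ld_source.variant_index()
    for v in (variant_a, variant_b):
        if v not in idx:
            raise KeyError(f"variant {v!r} not in LD source")
    a = ld_source.dosages[:, idx[variant_a]]
    b = ld_source.dosages[:, idx[variant_b]]
    return _r2_vec(a, b)


def _r2_vec(a: np.ndarray, b: np.ndarray) -> float:
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        logger.debug("monomorphic pair in r2; treated as 0")
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class _Locus:
    chrom: str
    snps: pd.DataFrame  # columns id, pos, p (significant members)

    @property
    def peak(self) -> pd.Series:
        # minimum p; ties broken by lowest position
        t = self.snps.sort_values(["p", "pos"], kind="stable")
        return t.iloc[0]

    @property
    def start(self) -> int:
        return int(self.snps["pos"].min())

    @property
    def end(self) -> int:
        return int(self.snps["pos"].max())


def _seed_loci(sig: pd.DataFrame, group_dist_bp: int) -> list[_Locus]:
    loci = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable").reset_index(drop=True)
        gaps = sub["pos"].diff().to_numpy()
        breaks = np.flatnonzero(gaps >= group_dist_bp)
        start = 0
        for b in list(breaks) + [len(sub)]:
            loci.append(_Locus(str(chrom), sub.iloc[start:b].reset_index(drop=True)))
            start = b
    return [l for l in loci if len(l.snps)]


def _mergeable(
    a: _Locus, b: _Locus, r2_cache: dict, dosage_of, cfg: AnalysisConfig
) -> bool:
    if a.chrom != b.chrom:
        return False
    if abs(int(a.peak["pos"]) - int(b.peak["pos"])) >= cfg.merge_dist_bp:
        return False
    for ia in a.snps["id"]:
        for ib in b.snps["id"]:
            key = (ia, ib) if ia <= ib else (ib, ia)
            if key not in r2_cache:
                da, db = dosage_of(ia), dosage_of(ib)
                r2_cache[key] = (
                    _r2_vec(da, db) if da is not None and db is not None else 0.0
                )
            if r2_cache[key] > cfg.ld_r2:
                return True
    return False


def _merge_to_closure(
    loci: list[_Locus], dosage_of, cfg: AnalysisConfig
) -> list[_Locus]:
    loci = sorted(loci, key=lambda l: (l.chrom, l.start))
    r2_cache: dict = {}
    merged = True
    while merged:
        merged = False
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                if _mergeable(loci[i], loci[j], r2_cache, dosage_of, cfg):
                    combined = _Locus(
                        loci[i].chrom,
                        pd.concat([loci[i].snps, loci[j].snps])
                        .sort_values("pos", kind="stable")
                        .reset_index(drop=True),
                    )
                    loci = (
                        loci[:i] + [combined] + loci[i + 1 : j] + loci[j + 1 :]
                    )
                    loci.sort(key=lambda l: (l.chrom, l.start))
                    merged = True
                    break
            if merged:
                break
    return loci


def call_qtls(
    gwas,
    ld_source: GenotypeMatrix,
    cfg: AnalysisConfig | None = None,
) -> list[QTL]:
    """Run the full grouping / LD-merge / peak-extension caller.

    ``gwas`` is a GWASResult (or a DataFrame with id, chrom, pos, p).
    SNPs absent from ``ld_source`` contribute r^2 = 0 to merge decisions
    (warning).
    """
    cfg = cfg or AnalysisConfig()
    table = gwas.table if hasattr(gwas, "table") else gwas
    population = getattr(gwas, "population", "")
    trait = getattr(gwas, "trait", "")
    sig = table[table["p"] <= cfg.sig_p][["id", "chrom", "pos", "p"]]
    if sig.empty:
        return []

    vindex = ld_source.variant_index()
    warned = [False]

    def dosage_of(vid):
        j = vindex.get(vid)
        if j is None:
            if not warned[0]:
                logger.warning("variant %s absent from LD source; r2 -> 0", vid)
                warned[0] = True
            return None
        return ld_source.dosages[:, j]

    loci = _seed_loci(sig, cfg.group_dist_bp)
    loci = _merge_to_closure(loci, dosage_of, cfg)

    out: list[QTL] = []
    for locus in loci:
        n_sig = len(locus.snps)
        if n_sig >= cfg.min_snps:
            out.append(_emit(locus, n_sig, "significant", population, trait))
            continue
        # single extension: +/- ext_bp around the locus, suggestive tier
        lo = locus.start - cfg.ext_bp
        hi = locus.end + cfg.ext_bp
        near = table[
            (table["chrom"] == locus.chrom)
            & (table["pos"] >= lo)
            & (table["pos"] <= hi)
            & (table["p"] <= cfg.suggestive_p)
        ][["id", "pos", "p"]]
        if len(near) >= cfg.min_snps:
            ext = _Locus(
                locus.chrom,
                near.sort_values("pos", kind="stable").reset_index(drop=True),
            )
            out.append(_emit(ext, len(near), "suggestive", population, trait))
        # else dropped
    out.sort(key=lambda q: (q.chrom, q.start))
    return out


def _emit(locus: _Locus, n: int, support: str, population: str, trait: str) -> QTL:
    peak = locus.peak
    return QTL(
        chrom=locus.chrom,
        start=locus.start,
        end=locus.end,
        peak_id=str(peak["id"]),
        peak_pos=int(peak["pos"]),
        peak_p=float(peak["p"]),
        n_sig_snps=n,
        support=support,
        population=population,
        trait=trait,
    )


# ---------------------------------------------------------------------------
# Cross-population merging
# ---------------------------------------------------------------------------

@dataclass
class MergedQTL:
    """Union span of overlapping per-population QTLs."""

    chrom: str
    start: int
    end: int
    members: list[QTL]

    @property
    def populations(self) -> list[str]:
        return sorted({q.population for q in self.members})

    @property
    def n_detections(self) -> int:
        return len(self.members)

    @property
    def best_peak(self) -> QTL:
        return min(self.members, key=lambda q: (q.peak_p, q.peak_pos))


def merge_across_populations(qtl_lists: list[list[QTL]]) -> list[MergedQTL]:
    """Transitive closure of interval overlap across population QTL maps."""
    qtls = [q for lst in qtl_lists for q in lst]
    qtls.sort(key=lambda q: (q.chrom, q.start, q.end))
    merged: list[MergedQTL] = []
    for q in qtls:
        if (
            merged
            and merged[-1].chrom == q.chrom
            and q.start <= merged[-1].end
        ):
            merged[-1].end = max(merged[-1].end, q.end)
            merged[-1].members.append(q)
        else:
            merged.append(MergedQTL(q.chrom, q.start, q.end, [q]))
    return merged


# ---------------------------------------------------------------------------
# Heterotic classification
# ---------------------------------------------------------------------------

ADDITIVE = "additive"
DOMINANT = "dominant"
EPISTATIC_DXA = "epistatic_DxA"
EPISTATIC_DXD = "epistatic_DxD"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class QTLClass:
    detected_maternal: bool
    detected_f1: bool
    detected_mph: bool
    label: str
    flag: str = ""


def classify_heterotic_qtl(
    detected_maternal: bool, detected_f1: bool, detected_mph: bool
) -> QTLClass:
    """Map the (maternal, F1, MPH) detection pattern to a heterotic class.

    A locus seen in both the maternal inbreds and the F1 hybrids acts
    additively; one seen in maternal lines but only re-emerging in the
    MPH signal reflects dominance complementation; loci invisible in the
    maternal panel but detected in the F1 (or only in MPH) indicate the
    masking allele is complemented by the tester, i.e. epistatic
    (dominance-by-additive / dominance-by-dominance) effects.
    """
    m, f1, mph = bool(detected_maternal), bool(detected_f1), bool(detected_mph)
    table = {
        (True, True, False): (ADDITIVE, ""),
        (True, True, True): (ADDITIVE, "with-dominance"),
        (True, False, True): (DOMINANT, ""),
        (True, False, False): (UNCLASSIFIED, "maternal-only"),
        (False, True, False): (EPISTATIC_DXA, ""),
        (False, True, True): (EPISTATIC_DXA, "subtype-ambiguous"),
        (False, False, True): (EPISTATIC_DXD, ""),
        (False, False, False): (UNCLASSIFIED, ""),
    }
    label, flag = table[(m, f1, mph)]
    return QTLClass(m, f1, mph, label, flag)


def classify_merged_map(
    maternal_qtls: list[QTL],
    f1_qtls: list[QTL],
    mph_qtls: list[QTL],
) -> pd.DataFrame:
    """Merge the three per-source QTL maps and classify every interval.

    Returns one row per merged QTL: chrom, start, end, the three
    detection booleans, class label and flag, plus the best peak id.
    """
    tagged: list[QTL] = []
    source_of: dict[int, str] = {}
    for src, lst in (
        ("maternal", maternal_qtls),
        ("f1", f1_qtls),
        ("mph", mph_qtls),
    ):
        for q in lst:
            tagged.append(q)
            source_of[id(q)] = src
    merged = merge_across_populations([tagged])
    rows = []
    for mq in merged:
        sources = {source_of[id(q)] for q in mq.members}
        cls = classify_heterotic_qtl(
            "maternal" in sources, "f1" in sources, "mph" in sources
        )
        rows.append(
            {
                "chrom": mq.chrom,
                "start": mq.start,
                "end": mq.end,
                "detected_maternal": cls.detected_maternal,
                "detected_f1": cls.detected_f1,
                "detected_mph": cls.detected_mph,
                "class": cls.label,
                "flag": cls.flag,
                "peak_id": mq.best_peak.peak_id,
                "peak_p": mq.best_peak.peak_p,
                "n_detections": mq.n_detections,
            }
        )
    return pd.DataFrame(rows)


def cumulative_class_effects(
    classified: pd.DataFrame,
    merged: list[MergedQTL],
    gwas_results: dict[tuple[str, str], "object"],
) -> pd.DataFrame:
    """Per-trait, per-class cumulative |peak effect|.

    For each merged QTL, |beta| at its peak SNP is averaged over the
    populations where it was detected, then summed within (trait,
    class). QTLs whose peak beta cannot be looked up are skipped and
    logged.
    """
    coarse = {ADDITIVE: ADDITIVE, DOMINANT: DOMINANT,
              EPISTATIC_DXA: "epistatic", EPISTATIC_DXD: "epistatic"}
    acc: dict[tuple[str, str], float] = {}
    for i, mq in enumerate(merged):
        label = coarse.get(classified.iloc[i]["class"])
        if label is None:
            continue
        betas = []
        for q in mq.members:
            res = gwas_results.get((q.population, q.trait))
            if res is None:
                continue
            hit = res.table[res.table["id"] == q.peak_id]
            if hit.empty:
                logger.warning("peak %s missing beta; QTL member skipped", q.peak_id)
                continue
            betas.append(abs(float(hit["beta"].iloc[0])))
        if not betas:
            continue
        traits = {q.trait for q in mq.members} or {""}
        for trait in traits:
            key = (trait, label)
            acc[key] = acc.get(key, 0.0) + float(np.mean(betas))
    rows = [
        {"trait": t, "class": c, "cumulative_abs_beta": v}
        for (t, c), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["trait", "class", "cumulative_abs_beta"])


def qtl_table(qtls: list[QTL]) -> pd.DataFrame:
    """QTL list as the canonical TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "peak_id": q.peak_id,
                "peak_pos": q.peak_pos,
                "peak_p": q.peak_p,
                "n_snps": q.n_sig_snps,
                "support": q.support,
                "population": q.population,
                "trait": q.trait,
            }
            for q in qtls
        ]
    )
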