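"""NC-II factorial design: cross enumeration, training splits, the five
parental SNP filters, and F1 genotype inference.

The NC-II (North Carolina II) design crosses every maternal inbred line
to every paternal tester; one tester defines one half-sib F1 population.
Because parents are inbred, the F1 dosage at a site where both parents
are homozygous is simply the mean of the parental dosages; a
heterozygous or missing parental call makes the derived F1 call missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, VariantInfo, compute_maf

logger = logging.getLogger("hybridforge")


def cross_id(maternal: str, paternal: str) -> str:
    """Canonical F1 sample id for a maternal x paternal cross."""
    return f"{maternal}_x_{paternal}"


@dataclass
class CrossDesign:
    """The factorial of crosses plus an optional training mask."""

    maternal_ids: list[str]
    paternal_ids: list[str]
    crosses: list[tuple[str, str]]
    training_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        mset, pset = set(self.maternal_ids), set(self.paternal_ids)
        if len(mset) != len(self.maternal_ids) or len(pset) != len(self.paternal_ids):
            raise ValueError("parent ids must be unique")
        if mset & pset:
            raise ValueError(
                f"maternal/paternal pools overlap: {sorted(mset & pset)[:5]}"
            )
        seen = set()
        for m, p in self.crosses:
            if m not in mset or p not in pset:
                raise ValueError(f"cross ({m}, {p}) references unknown parent")
            if (m, p) in seen:
                raise ValueError(f"duplicate cross ({m}, {p})")
            seen.add((m, p))
        if self.training_mask is not None:
            self.training_mask = np.asarray(self.training_mask, dtype=bool)
            if self.training_mask.shape != (len(self.crosses),):
                raise ValueError("training mask length != number of crosses")

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def cross_ids(self) -> list[str]:
        return [cross_id(m, p) for m, p in self.crosses]

    def training_crosses(self) -> list[tuple[str, str]]:
        if self.training_mask is None:
            raise ValueError("no training mask set")
        return [c for c, t in zip(self.crosses, self.training_mask) if t]

    def candidate_crosses(self) -> list[tuple[str, str]]:
        if self.training_mask is None:
            raise ValueError("no training mask set")
        return [c for c, t in zip(self.crosses, self.training_mask) if not t]


def enumerate_crosses(
    maternal_ids: list[str], paternal_ids: list[str]
) -> CrossDesign:
    """Full NC-II factorial in deterministic maternal-major order."""
    if not maternal_ids or not paternal_ids:
        raise ValueError("both parental pools must be non-empty")
    crosses = [(m, p) for m in maternal_ids for p in paternal_ids]
    return CrossDesign(list(maternal_ids), list(paternal_ids), crosses)


def make_training_split(
    design: CrossDesign,
    full_testers: list[str],
    maternal_subset: list[str],
) -> CrossDesign:
    """Mark the phenotyped training block of an NC-II factorial.

    Training = (all maternal lines x ``full_testers``) union
    (``maternal_subset`` x all remaining testers); everything else is the
    unphenotyped candidate set to be predicted.
    """
    bad = set(full_testers) - set(design.paternal_ids)
    if bad:
        raise ValueError(f"full_testers not in paternal pool: {sorted(bad)}")
    bad = set(maternal_subset) - set(design.maternal_ids)
    if bad:
        raise ValueError(f"maternal_subset not in maternal pool: {sorted(bad)}")
    full = set(full_testers)
    sub = set(maternal_subset)
    mask = np.array(
        [(p in full) or (m in sub) for m, p in design.crosses], dtype=bool
    )
    if not mask.any():
        raise ValueError("training split is empty")
    return CrossDesign(
        design.maternal_ids, design.paternal_ids, list(design.crosses), mask
    )


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Survivorship of the five-step parental SNP filter.

    Criterion 1 flags heterozygous parental *cells* (they become missing
    in the derived F1 genotypes) and removes nothing; criteria 2-5 remove
    whole variants, applied in order.
    """

    n_input: int
    het_cells_flagged: int
    removed_het_rate: int          # criterion 2
    removed_monomorphic: int       # criterion 3
    removed_low_maf: int           # criterion 4
    removed_rare_homozygote: int   # criterion 5
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.removed_het_rate
            + self.removed_monomorphic
            + self.removed_low_maf
            + self.removed_rare_homozygote
            + self.n_retained
        )
        assert total == self.n_input, "filter counts do not add up"


def filter_parent_snps(
    parents: GenotypeMatrix,
    maternal_ids: list[str],
    paternal_ids: list[str],
    maf_min: float = 0.02,
    maternal_het_max: float = 0.10,
    paternal_het_max: float = 1.0 / 30.0,
    rare_homo_frac: float = 0.005,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the five parental SNP filters, in order.

    1. heterozygous parental calls flagged (cell-level; the derived F1
       call at that cross will be missing) -- reported, not removed;
    2. remove variants with het rate >= 10% among maternal lines or
       >= 1/30 among paternal lines;
    3. remove variants monomorphic within the maternal pool or within
       the paternal pool;
    4. remove variants with MAF < 0.02 over all parental lines jointly;
    5. remove variants whose minor homozygous F1 genotype, over the full
       maternal x paternal factorial, would occur in < 0.5% of hybrids.

    Returns the filtered matrix (MAF refreshed) and a FilterReport.
    Re-running the filter on its own output removes nothing.
    """
    idx = {s: i for i, s in enumerate(parents.sample_ids)}
    absent = [s for s in list(maternal_ids) + list(paternal_ids) if s not in idx]
    if absent:
        raise ValueError(f"design parents absent from matrix: {absent[:5]}")
    M = parents.dosages[[idx[s] for s in maternal_ids]]
    P = parents.dosages[[idx[s] for s in paternal_ids]]
    m_in = parents.n_variants

    het_cells = int((M == 1).sum() + (P == 1).sum())

    def _het_rate(X: np.ndarray) -> np.ndarray:
        obs = np.isfinite(X).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs > 0, (X == 1).sum(axis=0) / obs, 0.0)

    alive = np.ones(m_in, dtype=bool)

    # criterion 2: excess residual heterozygosity in either pool
    c2 = (_het_rate(M) >= maternal_het_max) | (_het_rate(P) >= paternal_het_max)
    removed_c2 = int((alive & c2).sum())
    alive &= ~c2

    # criterion 3: monomorphic within either pool (ignoring missing)
    def _mono(X: np.ndarray) -> np.ndarray:
        mn = np.nanmin(np.where(np.isfinite(X), X, np.inf), axis=0)
        mx = np.nanmax(np.where(np.isfinite(X), X, -np.inf), axis=0)
        return ~(mx > mn)  # all-missing counts as monomorphic

    c3 = _mono(M) | _mono(P)
    removed_c3 = int((alive & c3).sum())
    alive &= ~c3

    # criterion 4: MAF over all parental lines jointly
    all_par = np.vstack([M, P])
    with np.errstate(invalid="ignore"):
        p = np.nanmean(all_par, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    c4 = ~(maf >= maf_min)  # NaN maf fails too
    removed_c4 = int((alive & c4).sum())
    alive &= ~c4

    # criterion 5: minor homozygous F1 genotype over the FULL factorial.
    # With homozygous-only transmission, F1 dosage 0 needs maternal 0 and
    # paternal 0; dosage 2 needs 2 and 2; counts factorize.
    n_f1 = len(maternal_ids) * len(paternal_ids)
    count0 = (M == 0).sum(axis=0) * (P == 0).sum(axis=0)
    count2 = (M == 2).sum(axis=0) * (P == 2).sum(axis=0)
    c5 = np.minimum(count0, count2) < rare_homo_frac * n_f1
    removed_c5 = int((alive & c5).sum())
    alive &= ~c5

    report = FilterReport(
        n_input=m_in,
        het_cells_flagged=het_cells,
        removed_het_rate=removed_c2,
        removed_monomorphic=removed_c3,
        removed_low_maf=removed_c4,
        removed_rare_homozygote=removed_c5,
        n_retained=int(alive.sum()),
    )
    logger.info(
        "SNP filter: %d in -> %d retained (het-rate %d, monomorphic %d, "
        "low-MAF %d, rare-homozygote %d removed; %d het cells flagged)",
        m_in, report.n_retained, removed_c2, removed_c3, removed_c4,
        removed_c5, het_cells,
    )
    return parents.subset_variants(alive).with_maf(), report


def infer_f1_genotypes(
    parents: GenotypeMatrix, design: CrossDesign
) -> GenotypeMatrix:
    """Derive F1 dosages from homozygous parental dosages.

    f1 = (maternal + paternal) / 2 when both parental calls are
    homozygous (0 or 2); a heterozygous or missing parental call yields a
    missing F1 call. Output samples are the design's crosses in order.
    """
    idx = {s: i for i, s in enumerate(parents.sample_ids)}
    for m, p in design.crosses:
        if m not in idx or p not in idx:
            raise ValueError(f"cross parent missing from genotype matrix: {m}, {p}")
    M = parents.dosages[[idx[m] for m, _ in design.crosses]]
    P = parents.dosages[[idx[p] for _, p in design.crosses]]
    ok = np.isin(M, (0.0, 2.0)) & np.isin(P, (0.0, 2.0))
    f1 = np.where(ok, (M + P) / 2.0, np.nan)
    return GenotypeMatrix(design.cross_ids(), list(parents.variants), f1)


def impute_f1_missing(
    f1: GenotypeMatrix, design: CrossDesign
) -> GenotypeMatrix:
    """Fill missing F1 calls with the modal dosage of the tester group.

    For each variant, within the half-sib family sharing one paternal
    tester, missing cells take the most frequent observed dosage; ties
    break toward the lower dosage. Variants entirely missing within a
    group stay missing (warning). A deterministic stand-in for
    haplotype-based imputation, flagged as such in the log.
    """
    if f1.sample_ids != design.cross_ids():
        raise ValueError("F1 matrix samples do not match design crosses")
    X = f1.dosages.copy()
    testers = np.array([p for _, p in design.crosses])
    n_filled = 0
    n_unfillable = 0
    for tester in design.paternal_ids:
        rows = np.flatnonzero(testers == tester)
        block = X[rows]
        miss = np.isnan(block)
        cols = np.flatnonzero(miss.any(axis=0))
        for j in cols:
            col = block[:, j]
            obs = col[np.isfinite(col)]
            if obs.size == 0:
                n_unfillable += 1
                continue
            counts = [(obs == d).sum() for d in (0.0, 1.0, 2.0)]
            mode = float(np.argmax(counts))  # argmax takes lowest on ties
            col[np.isnan(col)] = mode
            n_filled += int(miss[:, j].sum())
            block[:, j] = col
        X[rows] = block
    logger.info(
        "mode-fill imputation: %d cells filled, %d variant/tester groups "
        "unfillable (left missing)",
        n_filled, n_unfillable,
    )
    if n_unfillable:
        logger.warning("%d variant/tester groups had no observed calls", n_unfillable)
    return GenotypeMatrix(list(f1.sample_ids), list(f1.variants), X)
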