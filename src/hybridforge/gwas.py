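"""Mixed-linear-model association scans with kinship correction.

Each scan fits the null model y = X beta + u + e with u ~ N(0, K
sigma_u^2) once per (population, trait), then tests every variant by
generalized least squares in the eigenrotated space, holding the
variance ratio at its null REML estimate (the standard
population-parameters-previously-determined approximation). The Wald
statistic uses a t reference with n - c - 1 degrees of freedom, so with
an identity kinship and intercept-only covariates the scan reduces
exactly to the simple-regression t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import SpectralREML, fit_reml
from .config import AnalysisConfig
from .gblup import GRM
from .io import GenotypeMatrix, mean_fill

logger = logging.getLogger("hybridforge")


@dataclass
class GWASResult:
    """Per-variant association results for one population x trait."""

    population: str
    trait: str
    table: pd.DataFrame  # columns: id, chrom, pos, beta, se, p
    n_samples: int
    sigma_u2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        req = {"id", "chrom", "pos", "beta", "se", "p"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS table missing columns: {sorted(missing)}")

    def significant(self, p_cut: float) -> pd.DataFrame:
        return self.table[self.table["p"] <= p_cut]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def fit_null_lmm(y, covariates, grm: GRM, sample_ids: list[str]) -> SpectralREML:
    """REML fit of the polygenic null model on one population.

    ``covariates`` excludes the intercept, which is always added.
    Returns the spectral fit whose cached rotation the scan reuses.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = _with_intercept(covariates, y.size)
    K = grm.submatrix(sample_ids, sample_ids)
    return fit_reml(y, X, K)


def _with_intercept(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return np.column_stack([np.ones(n), C])


def association_scan(
    gm: GenotypeMatrix,
    y,
    grm: GRM | None,
    covariates=None,
    population: str = "",
    trait: str = "",
    exact: bool = False,
) -> GWASResult:
    """Scan every variant of ``gm`` against ``y``.

    With ``grm=None`` the polygenic term is dropped and the scan is
    plain per-variant linear regression (used by the spike-in
    simulations, whose traits have no polygenic background). With
    ``exact=True`` the variance ratio is re-optimized per variant
    instead of being held at the null estimate.

    Missing dosages are mean-filled for testing; monomorphic variants
    are reported with beta 0 and p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    if gm.n_samples != y.size:
        raise ValueError(
            f"genotype matrix has {gm.n_samples} samples but y has {y.size}"
        )
    X = _with_intercept(covariates, y.size)
    if grm is None:
        table = _scan_rotated(
            mean_fill(gm.dosages), y, X, np.ones(y.size), gm
        )
        sigma_u2, sigma_e2 = 0.0, float("nan")
    else:
        null = fit_null_lmm(
            y, None if covariates is None else covariates, grm, gm.sample_ids
        )
        G = mean_fill(gm.dosages)
        if exact:
            table = _scan_exact(G, y, X, null, gm)
        else:
            sq = np.sqrt(null.weights)
            G_rot = null.U.T @ G
            table = _scan_rotated(
                sq[:, None] * G_rot, sq * null.y_rot, sq[:, None] * null.X_rot,
                None, gm,
            )
        sigma_u2, sigma_e2 = null.sigma_u2, null.sigma_e2
    return GWASResult(population, trait, table, y.size, sigma_u2, sigma_e2)


def _scan_rotated(G, y, X, weights, gm: GenotypeMatrix) -> pd.DataFrame:
    """Vectorized per-variant GLS in an (already whitened) space.

    For each variant g, regress y on [X, g]; Wald t on n - c - 1 df.
    """
    if weights is not None:
        sq = np.sqrt(weights)
        G = sq[:, None] * G
        y = sq * y
        X = sq[:, None] * X
    n, c = X.shape
    df = n - c - 1
    if df < 1:
        raise ValueError("not enough samples for the scan")
    XtX_inv = np.linalg.inv(X.T @ X)
    A = X @ XtX_inv  # n x c
    # residual-maker products: P = I - X (X'X)^{-1} X'
    Py = y - A @ (X.T @ y)
    XtG = X.T @ G  # c x m
    PG = G - A @ XtG
    gPg = np.einsum("ij,ij->j", G, PG)
    gPy = G.T @ Py
    yPy = float(y @ Py)
    poly = gPg > 1e-12 * max(1.0, float(np.max(np.abs(G))) ** 2 * n)
    beta = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.nan)
    p = np.ones(G.shape[1])
    b = gPy[poly] / gPg[poly]
    rss = yPy - b * gPy[poly] * 1.0  # = yPy - b^2 gPg
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / df
    se_b = np.sqrt(np.where(sigma2 > 0, sigma2 / gPg[poly], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_b > 0, b / se_b, np.inf * np.sign(b))
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    beta[poly] = b
    se[poly] = se_b
    p[poly] = np.maximum(pv, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "id": [v.id for v in gm.variants],
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "beta": beta,
            "se": se,
            "p": p,
        }
    )


def _scan_exact(G, y, X, null: SpectralREML, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant re-optimized REML scan (small panels only)."""
    rows = []
    K_eig = (null.U, null.s)
    for j, v in enumerate(gm.variants):
        g = G[:, j]
        if np.ptp(g) == 0.0:
            rows.append((v.id, v.chrom, v.pos, 0.0, np.nan, 1.0))
            continue
        Xg = np.column_stack([X, g])
        U, s = K_eig
        res = fit_reml(y, Xg, U @ np.diag(s) @ U.T)
        b, se_b = res.beta[-1], res.beta_se[-1]
        df = len(y) - Xg.shape[1]
        t = b / se_b if se_b > 0 else np.inf
        pv = max(2.0 * stats.t.sf(abs(t), df), np.finfo(float).tiny)
        rows.append((v.id, v.chrom, v.pos, b, se_b, pv))
    return pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "beta", "se", "p"]
    )


# ---------------------------------------------------------------------------
# Conditional GWAS
# ---------------------------------------------------------------------------

@dataclass
class SubgroupSplit:
    """Partition of samples by homozygous genotype at a tag SNP."""

    tag_id: str
    groups: dict[str, list[str]]  # class label -> sample ids
    excluded: list[str]           # het or missing at the tag

    def __post_init__(self) -> None:
        all_ids = [s for g in self.groups.values() for s in g] + self.excluded
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("subgroup classes overlap")


def split_by_tag(gm: GenotypeMatrix, tag_variant: str) -> SubgroupSplit:
    """Divide samples into the two homozygote classes at a tag SNP."""
    j = gm.variant_index().get(tag_variant)
    if j is None:
        raise KeyError(f"tag variant {tag_variant!r} not in matrix")
    d = gm.dosages[:, j]
    groups = {}
    for dosage, label in ((0.0, "ref"), (2.0, "alt")):
        ids = [s for s, x in zip(gm.sample_ids, d) if x == dosage]
        if ids:
            groups[label] = ids
    excluded = [s for s, x in zip(gm.sample_ids, d) if x not in (0.0, 2.0)]
    if len(groups) < 2:
        raise ValueError(f"tag variant {tag_variant!r} has a single homozygote class")
    return SubgroupSplit(tag_variant, groups, excluded)


def conditional_scan(
    gm: GenotypeMatrix,
    y: pd.Series,
    tag_variant: str,
    genotypes_for_grm: GenotypeMatrix | None = None,
    cfg: AnalysisConfig | None = None,
    population: str = "",
    trait: str = "",
) -> dict[str, GWASResult]:
    """Independent scans within each homozygote class at a tag SNP.

    The kinship matrix and null model are re-fitted per subgroup.
    Classes below ``cfg.min_subgroup`` samples are skipped with a
    warning; heterozygous/missing samples at the tag are excluded.
    ``y`` is indexed by sample id.
    """
    from .gblup import compute_cgrm

    cfg = cfg or AnalysisConfig()
    split = split_by_tag(gm, tag_variant)
    out = {}
    for label, ids in split.groups.items():
        ids = [s for s in ids if s in y.index]
        if len(ids) < cfg.min_subgroup:
            logger.warning(
                "subgroup %s at %s has %d (< %d) samples; skipped",
                label, tag_variant, len(ids), cfg.min_subgroup,
            )
            continue
        sub = gm.subset_samples(ids)
        grm_src = (
            genotypes_for_grm.subset_samples(ids)
            if genotypes_for_grm is not None
            else sub
        )
        grm = compute_cgrm(grm_src)
        out[label] = association_scan(
            sub, y.loc[ids].to_numpy(), grm,
            population=f"{population}|{tag_variant}={label}", trait=trait,
        )
    return out


# ---------------------------------------------------------------------------
# GWAS battery
# ---------------------------------------------------------------------------

def plan_battery(
    n_f1_populations: int,
    traits: list[str],
    mph_traits: list[str],
    maternal_traits: list[str] | None = None,
) -> int:
    """Number of scans: maternal traits + per-F1-population (traits + MPH)."""
    maternal_traits = traits if maternal_traits is None else maternal_traits
    return len(maternal_traits) + n_f1_populations * (
        len(traits) + len(mph_traits)
    )


def run_gwas_battery(
    maternal_gm: GenotypeMatrix,
    maternal_pheno: pd.DataFrame,
    f1_populations: dict[str, GenotypeMatrix],
    f1_pheno: dict[str, pd.DataFrame],
    traits: list[str],
    mph_traits: list[str] | None = None,
    with_kinship: bool = True,
) -> dict[tuple[str, str], GWASResult]:
    """One scan per (population, trait) cell.

    Populations are the maternal panel (scanned for ``traits``) plus
    each F1 half-sib family (scanned for ``traits`` and ``mph_traits``).
    Phenotype frames are indexed by sample id; cells whose trait column
    is absent are skipped and logged.
    """
    from .gblup import compute_cgrm

    mph_traits = mph_traits or []
    results: dict[tuple[str, str], GWASResult] = {}

    def _scan(pop, gm, pheno, trait):
        if trait not in pheno.columns:
            logger.warning("population %s lacks trait %s; cell skipped", pop, trait)
            return
        ids = [s for s in gm.sample_ids if s in pheno.index]
        sub = gm.subset_samples(ids) if len(ids) != gm.n_samples else gm
        yv = pheno.loc[ids, trait].to_numpy(dtype=float)
        keep = np.isfinite(yv)
        if not keep.all():
            ids = [s for s, k in zip(ids, keep) if k]
            sub = sub.subset_samples(ids)
            yv = yv[keep]
        grm = compute_cgrm(sub) if with_kinship else None
        results[(pop, trait)] = association_scan(
            sub, yv, grm, population=pop, trait=trait
        )

    for trait in traits:
        _scan("maternal", maternal_gm, maternal_pheno, trait)
    for pop, gm in f1_populations.items():
        pheno = f1_pheno[pop]
        for trait in list(traits) + list(mph_traits):
            _scan(pop, gm, pheno, trait)
    logger.info("GWAS battery: %d scans completed", len(results))
    return results
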