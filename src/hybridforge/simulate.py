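"""Synthetic data generation and the two spike-in QTN simulation studies.

The generator emulates a multi-parent maize panel: mostly-homozygous
inbred lines, biallelic SNPs laid out on 10 chromosomes with
block-structured LD (a latent Gaussian AR(1) within blocks, thresholded
to hit each variant's target allele frequency), and a MAF spectrum wide
enough to leave a 0.25-0.35 stratum for QTN spiking.

Simulation one quantifies GWAS false discovery rate and detection power
when the scanned phenotype is a *predicted* phenotype of accuracy r^2:
a 20-QTN trait with geometric effects beta_i = 0.96^i is built from the
genotypes, corrupted by prediction noise of variance var(y)(1-r^2)/r^2,
and scanned; detection power is read at permutation-based thresholds and
FDR at p <= 1e-5. Simulation two measures single-QTN power as a function
of effect size (in phenotypic SD units) and population size at the
genome-wide 2.2e-7 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .design import (
    CrossDesign,
    enumerate_crosses,
    infer_f1_genotypes,
    make_training_split,
)
from .io import GenotypeMatrix, TraitTable, VariantInfo, mean_fill

logger = logging.getLogger("hybridforge")


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------

def gen_inbred_genotypes(
    n_samples: int,
    n_variants: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_len: int = 25,
    block_rho: float = 0.95,
    residual_het_rate: float = 0.005,
    n_chrom: int = 10,
    spacing_bp: int = 50_000,
) -> GenotypeMatrix:
    """Simulate inbred-line dosages with block-structured LD.

    Variants are evenly spaced ``spacing_bp`` apart across ``n_chrom``
    chromosomes. Within a block of ``ld_block_len`` consecutive variants
    a per-sample latent AR(1) chain (correlation ``block_rho``) is
    thresholded at each variant's target frequency quantile, so
    neighbouring variants are in LD that decays with distance while the
    marginal allele frequency matches the requested spectrum. Lines are
    homozygous apart from ``residual_het_rate`` heterozygous calls.
    """
    rng = np.random.default_rng(seed)
    # block-coherent frequencies: SNPs in strong LD have similar allele
    # frequencies, so each block draws a base frequency from the spectrum
    # with small per-variant jitter
    n_blocks = int(np.ceil(n_variants / ld_block_len))
    base = rng.uniform(maf_range[0], maf_range[1], size=n_blocks)
    freqs = np.repeat(base, ld_block_len)[:n_variants]
    freqs = np.clip(
        freqs + rng.uniform(-0.02, 0.02, size=n_variants),
        maf_range[0], maf_range[1],
    )

    alleles = np.empty((n_samples, n_variants), dtype=float)
    start = 0
    while start < n_variants:
        stop = min(start + ld_block_len, n_variants)
        width = stop - start
        z = np.empty((n_samples, width))
        z[:, 0] = rng.standard_normal(n_samples)
        innov = rng.standard_normal((n_samples, width))
        for j in range(1, width):
            z[:, j] = block_rho * z[:, j - 1] + np.sqrt(1 - block_rho**2) * innov[:, j]
        thresh = stats.norm.ppf(freqs[start:stop])
        alleles[:, start:stop] = (z < thresh).astype(float)
        start = stop
    dosages = 2.0 * alleles
    if residual_het_rate > 0:
        het = rng.random(dosages.shape) < residual_het_rate
        dosages[het] = 1.0

    per_chrom = int(np.ceil(n_variants / n_chrom))
    variants = []
    for j in range(n_variants):
        # zero-padded names keep lexicographic == numeric chromosome order
        c = f"chr{j // per_chrom + 1:02d}"
        pos = (j % per_chrom + 1) * spacing_bp
        variants.append(VariantInfo(f"{c}.s_{pos}", c, pos, "A", "T"))
    samples = [f"L{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, variants, dosages).with_maf()


# ---------------------------------------------------------------------------
# QTN spiking
# ---------------------------------------------------------------------------

@dataclass
class QTNSet:
    """Spiked causal variants with geometric effects."""

    indices: np.ndarray
    effects: np.ndarray
    freqs: np.ndarray
    pve: np.ndarray | None = None
    classes: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.effects):
            raise ValueError("indices and effects lengths differ")


def spike_in_qtns(
    gm: GenotypeMatrix,
    n: int = 20,
    maf_window: tuple[float, float] = (0.25, 0.35),
    seed: int = 0,
    effect_base: float = 0.96,
) -> QTNSet:
    """Sample n QTNs uniformly from the MAF window; beta_i = 0.96^i.

    Effects are assigned by rank: the first drawn QTN gets 0.96^1, the
    last 0.96^n.
    """
    maf = np.array([v.maf for v in gm.variants])
    eligible = np.flatnonzero(
        (maf >= maf_window[0]) & (maf <= maf_window[1])
    )
    if eligible.size < n:
        raise ValueError(
            f"need {n} variants with maf in {maf_window}, found {eligible.size}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(eligible, size=n, replace=False)
    effects = effect_base ** np.arange(1, n + 1)
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(gm.dosages[:, idx], axis=0) / 2.0
    return QTNSet(idx, effects, freqs)


def genetic_value(gm: GenotypeMatrix, qtns: QTNSet) -> np.ndarray:
    """y = sum_i x_i beta_i over the spiked QTNs (no residual noise).

    Samples with a missing dosage at any QTN get a missing (NaN) value.
    """
    X = gm.dosages[:, qtns.indices]
    return X @ qtns.effects  # NaN propagates for missing dosages


def classify_pve(
    qtns: QTNSet,
    gm: GenotypeMatrix,
    major_cut: float = 0.07,
    moderate_cut: float = 0.045,
    mode: str = "normalized",
) -> QTNSet:
    """Attach per-QTN contribution shares and major/moderate/minor labels.

    The raw contribution is beta * f * (1 - f) with f the allele
    frequency in the analyzed samples; ``mode='normalized'`` (default)
    divides by the summed raw contributions so the 7% / 4.5% class
    boundaries act on fractions; ``'raw'`` thresholds the raw values;
    ``'variance'`` uses beta^2 * 2f(1-f) shares.
    """
    with np.errstate(invalid="ignore"):
        f = np.nanmean(gm.dosages[:, qtns.indices], axis=0) / 2.0
    if mode == "variance":
        raw = qtns.effects**2 * 2.0 * f * (1.0 - f)
    else:
        raw = qtns.effects * f * (1.0 - f)
    if mode in ("normalized", "variance"):
        tot = raw.sum()
        pve = raw / tot if tot > 0 else raw
    elif mode == "raw":
        pve = raw
    else:
        raise ValueError(f"unknown pve mode {mode!r}")
    classes = [
        "major" if v >= major_cut else "moderate" if v >= moderate_cut else "minor"
        for v in pve
    ]
    return QTNSet(qtns.indices, qtns.effects, f, pve, classes)


def add_prediction_noise(y: np.ndarray, r2: float, seed: int) -> np.ndarray:
    """Corrupt a phenotype to prediction accuracy r^2.

    y' = y + eps with eps ~ N(0, var(y) (1 - r^2) / r^2); r^2 = 1
    returns y unchanged.
    """
    if not (0.0 < r2 <= 1.0):
        raise ValueError(f"r2 must be in (0, 1], got {r2}")
    y = np.asarray(y, dtype=float)
    if r2 == 1.0:
        return y.copy()
    var = float(np.nanvar(y))
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, np.sqrt(var * (1.0 - r2) / r2), size=y.shape)


# ---------------------------------------------------------------------------
# Fast per-variant regression scan (no polygenic background)
# ---------------------------------------------------------------------------

def _fast_scan_p(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Simple-regression p-values for every column of G against y."""
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    gss = (Gc**2).sum(axis=0)
    yss = float(yc @ yc)
    num = Gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((gss > 0) & (yss > 0), num / np.sqrt(gss * yss), 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = df * r**2 / (1.0 - r**2)
    p = stats.t.sf(np.sqrt(t2), df) * 2.0
    return np.where((gss > 0) & (yss > 0), np.maximum(p, np.finfo(float).tiny), 1.0)


def permutation_threshold(
    G: np.ndarray,
    y: np.ndarray,
    alphas,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-based genome-wide significance thresholds.

    Shuffles y ``n_perm`` times, records the minimum scan p-value of each
    permutation, and returns the alpha-quantiles of those minima (one
    threshold per requested alpha). Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    n = y.size
    Gc = G - G.mean(axis=0)
    norms = np.sqrt((Gc**2).sum(axis=0))
    ok = norms > 0
    Gn = Gc[:, ok] / norms[ok]
    Y = np.empty((n, n_perm))
    for k in range(n_perm):
        Y[:, k] = y[rng.permutation(n)]
    Yc = Y - Y.mean(axis=0)
    ynorm = np.sqrt((Yc**2).sum(axis=0))
    R = Gn.T @ (Yc / ynorm)  # m x n_perm correlations
    rmax = np.clip(np.abs(R).max(axis=0), 0.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = df * rmax**2 / (1.0 - rmax**2)
    min_p = np.maximum(2.0 * stats.t.sf(np.sqrt(t2), df), np.finfo(float).tiny)
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    return np.quantile(min_p, alphas)


# ---------------------------------------------------------------------------
# Matching scan hits to spiked QTNs
# ---------------------------------------------------------------------------

def match_hits_to_qtns(
    sig_idx: np.ndarray,
    qtns: QTNSet,
    gm: GenotypeMatrix,
    cfg: AnalysisConfig | None = None,
) -> tuple[set[int], int]:
    """Cluster significant variants into loci; split true/false.

    ``sig_idx`` are variant column indices deemed significant. Loci are
    maximal runs of significant SNPs with gaps < the QTL grouping
    distance; a locus is a true detection when it contains a spiked QTN
    or any member SNP with r^2 > 0.1 to one. Returns (set of detected
    QTN indices N0, count of false loci N1).
    """
    cfg = cfg or AnalysisConfig()
    if len(sig_idx) == 0:
        return set(), 0
    sig_idx = np.sort(np.asarray(sig_idx))
    chroms = np.array([gm.variants[j].chrom for j in sig_idx])
    pos = np.array([gm.variants[j].pos for j in sig_idx])
    # maximal runs per chromosome
    loci: list[np.ndarray] = []
    start = 0
    for k in range(1, len(sig_idx) + 1):
        if (
            k == len(sig_idx)
            or chroms[k] != chroms[k - 1]
            or pos[k] - pos[k - 1] >= cfg.group_dist_bp
        ):
            loci.append(sig_idx[start:k])
            start = k
    qtn_set = set(int(i) for i in qtns.indices)
    Q = mean_fill(gm.dosages[:, qtns.indices])
    Qc = Q - Q.mean(axis=0)
    qn = np.sqrt((Qc**2).sum(axis=0))
    detected: set[int] = set()
    n_false = 0
    for members in loci:
        hit = qtn_set & set(int(j) for j in members)
        if hit:
            detected |= hit
            continue
        D = mean_fill(gm.dosages[:, members])
        Dc = D - D.mean(axis=0)
        dn = np.sqrt((Dc**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (Dc.T @ Qc) / np.outer(dn, qn)
        R = np.nan_to_num(R)
        linked = np.flatnonzero((R**2 > cfg.ld_r2).any(axis=0))
        if linked.size:
            detected |= {int(qtns.indices[q]) for q in linked}
        else:
            n_false += 1
    return detected, n_false


# ---------------------------------------------------------------------------
# Simulation one
# ---------------------------------------------------------------------------

@dataclass
class SimOneConfig:
    """Grid for the predicted-phenotype FDR/power study.

    Defaults are the full study conditions (36 grid cells x 500 reps on
    100,000 variants); :meth:`reduced` gives a desk-scale preset.
    """

    n_qtns: int = 20
    population_sizes: tuple = (207, 400, 600, 800, 1000, 1428)
    accuracy_levels: tuple = (1.0, 0.8, 0.6, 0.4, 0.2, 0.1)
    reps: int = 500
    n_variants: int = 100_000
    fdr_p: float = 1e-5
    alphas: tuple = (0.05,)
    n_perm: int = 1000
    maf_window: tuple = (0.25, 0.35)
    seed: int = 0

    @property
    def grid_size(self) -> int:
        return len(self.population_sizes) * len(self.accuracy_levels)

    @property
    def total_scans(self) -> int:
        return self.grid_size * self.reps

    @classmethod
    def reduced(cls, seed: int = 0) -> "SimOneConfig":
        return cls(
            population_sizes=(207, 800),
            accuracy_levels=(1.0, 0.4, 0.1),
            reps=50,
            n_variants=2000,
            n_perm=100,
            seed=seed,
        )


@dataclass
class SimGrid:
    """FDR and detection power per (size, r^2, alpha, QTN class)."""

    table: pd.DataFrame  # size, r2, alpha, qtn_class, power, fdr

    def power(self, size, r2, qtn_class="all", alpha=None) -> float:
        t = self.table
        sel = (t["size"] == size) & (t["r2"] == r2) & (t["qtn_class"] == qtn_class)
        if alpha is not None:
            sel &= t["alpha"] == alpha
        return float(t[sel]["power"].mean())

    def fdr(self, size, r2) -> float:
        t = self.table
        sel = (t["size"] == size) & (t["r2"] == r2)
        return float(t[sel]["fdr"].iloc[0])


def run_sim_one(cfg: SimOneConfig, gm: GenotypeMatrix) -> SimGrid:
    """Run the predicted-phenotype FDR/power grid.

    For every (population size, accuracy) cell and repetition: subsample
    the panel, spike a fresh QTN set, build the purely genetic phenotype,
    corrupt it to the target accuracy, scan all variants, then measure
    FDR at p <= ``cfg.fdr_p`` and detection power (per QTN class) at the
    permutation thresholds for each alpha. Cells report means over reps.
    """
    if max(cfg.population_sizes) > gm.n_samples:
        raise ValueError(
            f"panel has {gm.n_samples} samples; largest population size is "
            f"{max(cfg.population_sizes)}"
        )
    acfg = AnalysisConfig()
    master = np.random.default_rng(cfg.seed)
    rows = []
    for size in cfg.population_sizes:
        for r2 in cfg.accuracy_levels:
            fdrs = []
            power_acc: dict[tuple[float, str], list[float]] = {}
            for rep in range(cfg.reps):
                rseed = int(master.integers(2**31 - 1))
                rng = np.random.default_rng(rseed)
                rows_idx = rng.choice(gm.n_samples, size=size, replace=False)
                sub = GenotypeMatrix(
                    [gm.sample_ids[i] for i in rows_idx],
                    list(gm.variants),
                    gm.dosages[rows_idx],
                )
                qtns = spike_in_qtns(
                    gm, n=cfg.n_qtns, maf_window=cfg.maf_window, seed=rseed
                )
                qtns = classify_pve(qtns, sub)
                G = mean_fill(sub.dosages)
                y = G[:, qtns.indices] @ qtns.effects
                y_pred = add_prediction_noise(y, r2, seed=rseed + 1)
                p = _fast_scan_p(G, y_pred)

                # FDR at the fixed relaxed tier
                sig = np.flatnonzero(p <= cfg.fdr_p)
                detected, n_false = match_hits_to_qtns(sig, qtns, sub, acfg)
                n0 = len(detected)
                fdrs.append(n_false / (n_false + n0) if (n_false + n0) else 0.0)

                # power at permutation thresholds
                thr = permutation_threshold(
                    G, y_pred, cfg.alphas, n_perm=cfg.n_perm, seed=rseed + 2
                )
                for alpha, th in zip(cfg.alphas, thr):
                    sig_a = np.flatnonzero(p <= th)
                    det_a, _ = match_hits_to_qtns(sig_a, qtns, sub, acfg)
                    cls = np.array(qtns.classes)
                    hit = np.array(
                        [int(i) in det_a for i in qtns.indices]
                    )
                    for label in ("major", "moderate", "minor", "all"):
                        mask = cls == label if label != "all" else np.ones(len(cls), bool)
                        if mask.any():
                            power_acc.setdefault((alpha, label), []).append(
                                float(hit[mask].mean())
                            )
            mean_fdr = float(np.mean(fdrs))
            for (alpha, label), vals in sorted(power_acc.items()):
                rows.append(
                    {
                        "size": size,
                        "r2": r2,
                        "alpha": alpha,
                        "qtn_class": label,
                        "power": float(np.mean(vals)),
                        "fdr": mean_fdr,
                    }
                )
    return SimGrid(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Simulation two
# ---------------------------------------------------------------------------

@dataclass
class SimTwoConfig:
    """Single-QTN effect-gradient power study."""

    gradients: tuple = tuple(np.round(np.arange(0.1, 2.0, 0.1), 2))
    snps_per_gradient: int = 100
    threshold: float = 2.2e-7
    population_sizes: tuple = (207, 1428)
    maf_window: tuple = (0.25, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.gradients, dtype=float)
        if g.size == 0:
            raise ValueError("gradient list is empty")
        if not (np.diff(g) > 0).all():
            raise ValueError("gradients must be strictly increasing")

    @property
    def n_gradients(self) -> int:
        return len(self.gradients)

    @classmethod
    def reduced(cls, seed: int = 0) -> "SimTwoConfig":
        return cls(
            gradients=(0.2, 0.6, 1.0, 1.4),
            snps_per_gradient=40,
            population_sizes=(150, 600),
            seed=seed,
        )


def run_sim_two(
    cfg: SimTwoConfig, gm: GenotypeMatrix, base_phenotype: np.ndarray
) -> pd.DataFrame:
    """Power curves for a single spiked QTN over effect-size gradients.

    For every population size and gradient, ``snps_per_gradient`` SNPs
    in the MAF window are drawn; each defines a simulated phenotype by
    shifting the two genotype classes of that SNP apart by +/- (effect x
    SD of the base phenotype); the SNP passes when its own association
    p-value beats the genome-wide cutoff. Power is the passing fraction.
    Returns a DataFrame (size, effect, power).
    """
    y0 = np.asarray(base_phenotype, dtype=float)
    if y0.size != gm.n_samples:
        raise ValueError("base phenotype length != sample count")
    maf = np.array([v.maf for v in gm.variants])
    eligible = np.flatnonzero((maf >= cfg.maf_window[0]) & (maf <= cfg.maf_window[1]))
    master = np.random.default_rng(cfg.seed)
    rows = []
    for size in cfg.population_sizes:
        if size > gm.n_samples:
            raise ValueError(f"population size {size} exceeds panel")
        rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        keep = rng.choice(gm.n_samples, size=size, replace=False)
        ysub = y0[keep]
        sd = float(np.std(ysub))
        for effect in cfg.gradients:
            snps = rng.choice(eligible, size=cfg.snps_per_gradient, replace=False)
            n_pass = 0
            for j in snps:
                g = gm.dosages[keep, j]
                g = np.where(np.isfinite(g), g, np.nanmean(g))
                # split at the dosage midpoint into high/low classes
                high = g >= np.nanmean(g)
                y_sim = ysub + np.where(high, effect * sd, -effect * sd)
                p = _fast_scan_p(g[:, None], y_sim)[0]
                if p <= cfg.threshold:
                    n_pass += 1
            rows.append(
                {
                    "size": size,
                    "effect": float(effect),
                    "power": n_pass / cfg.snps_per_gradient,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full synthetic study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """A complete synthetic NC-II study with known causal architecture."""

    parents: GenotypeMatrix
    design: CrossDesign
    f1: GenotypeMatrix
    traits: TraitTable
    truth: pd.DataFrame  # trait, variant id, chrom, pos, kind, effect


def gen_full_study(
    seed: int,
    n_maternal: int = 250,
    n_testers: int = 4,
    n_variants: int = 2000,
    n_locations: int = 2,
    n_years: int = 2,
    residual_sd: float = 0.5,
    env_sd: float = 0.3,
    baseline: float = 100.0,
) -> StudyBundle:
    """Generate a small NC-II study with planted QTL architectures.

    Three traits mirror common architectures:

    * ``flowering`` -- three large purely additive QTLs (detected in
      maternal and F1 populations alike);
    * ``height`` -- one dominance-complemented QTL (testers fixed for
      the dominant allele, so it varies in maternal lines but not in
      hybrids) plus one epistatically masked pair: locus B's additive
      effect is expressed only on an activating background at locus A,
      which is rare in the maternal pool but fixed in the testers;
    * ``yield`` -- many small pairwise epistatic effects.

    Phenotypes are recorded per (location, year) with environment main
    effects and residual noise on top of the genetic value; units are
    arbitrary with a large positive baseline so mid-parent values stay
    away from zero. The ground-truth causal table is returned alongside.
    """
    rng = np.random.default_rng(seed)
    parents_all = gen_inbred_genotypes(
        n_maternal + n_testers, n_variants, seed=int(rng.integers(2**31 - 1)),
        block_rho=0.99, residual_het_rate=0.002,
    )
    maternal_ids = [f"M{i:04d}" for i in range(n_maternal)]
    paternal_ids = [f"T{i:02d}" for i in range(n_testers)]
    parents = GenotypeMatrix(
        maternal_ids + paternal_ids,
        list(parents_all.variants),
        parents_all.dosages.copy(),
    )

    per_chrom = int(np.ceil(n_variants / 10))
    block = 25

    def block_center(chrom_i: int, block_i: int) -> int:
        return chrom_i * per_chrom + block_i * block + block // 2

    mat_rows = np.arange(n_maternal)
    tes_rows = np.arange(n_maternal, n_maternal + n_testers)
    D = parents.dosages

    # pick causal variants at block centers, scanning forward for a block
    # whose center segregates well in the maternal pool (keeps LD intact
    # so the surrounding block tags the causal variant in scans)
    def pick(chrom_i, block_i):
        for off in range(per_chrom // block):
            j = block_center(chrom_i, (block_i + off) % (per_chrom // block))
            j = min(j, n_variants - 1)
            f = np.mean(D[mat_rows, j]) / 2.0
            if 0.2 <= f <= 0.8:
                return j
        return min(block_center(chrom_i, block_i), n_variants - 1)

    add_qtls = [pick(0, 2), pick(2, 5), pick(4, 8)]      # flowering
    dom_qtl = pick(1, 3)                                  # height, dominant
    epi_a = pick(6, 2)                                    # masking locus
    epi_b = pick(7, 6)                                    # masked locus
    yield_pairs = [(pick(3, 1), pick(5, 4)), (pick(8, 2), pick(9, 5))]

    # dominant locus: testers all carry the dominant (alt) allele
    D[tes_rows, dom_qtl] = 2.0
    # masking locus A: rare activator among maternal lines, fixed in testers
    D[mat_rows, epi_a] = np.where(rng.random(n_maternal) < 0.04, 2.0, 0.0)
    D[tes_rows, epi_a] = 2.0
    parents = GenotypeMatrix(parents.sample_ids, parents.variants, D).with_maf()

    design = enumerate_crosses(maternal_ids, paternal_ids)
    design = make_training_split(design, [paternal_ids[0]], maternal_ids[: n_maternal // 5])
    f1 = infer_f1_genotypes(parents, design)

    # --- genetic values ---
    def genetics(dosages: np.ndarray) -> dict[str, np.ndarray]:
        X = np.nan_to_num(dosages, nan=1.0)  # rare; midpoint fill
        flower = sum(1.2 * X[:, j] / 2.0 for j in add_qtls)
        dom = 2.0 * (X[:, dom_qtl] >= 1.0)
        masked = 2.2 * (X[:, epi_b] / 2.0) * (X[:, epi_a] >= 1.0)
        height = dom + masked
        yld = np.zeros(X.shape[0])
        for a, b in yield_pairs:
            yld = yld + 0.6 * (X[:, a] >= 1.0) * (X[:, b] / 2.0)
        return {
            "flowering": baseline + 3.0 * flower,
            "height": baseline + 10.0 * height,
            "yield": baseline + 5.0 * yld,
        }

    sample_sets = [
        (parents.sample_ids, genetics(parents.dosages)),
        (f1.sample_ids, genetics(f1.dosages)),
    ]

    records = []
    for loc in range(n_locations):
        for yr in range(n_years):
            env_seed = int(rng.integers(2**31 - 1))
            erng = np.random.default_rng(env_seed)
            for ids, gvals in sample_sets:
                for trait, g in gvals.items():
                    scale = {"flowering": 3.0, "height": 10.0, "yield": 5.0}[trait]
                    env_eff = erng.normal(0.0, env_sd * scale)
                    noise = erng.normal(0.0, residual_sd * scale, size=len(ids))
                    vals = g + env_eff + noise
                    for s, v in zip(ids, vals):
                        records.append(
                            {
                                "sample": s,
                                "trait": trait,
                                "location": f"loc{loc + 1}",
                                "year": 2014 + yr,
                                "value": float(v),
                            }
                        )
    traits = TraitTable(pd.DataFrame.from_records(records))

    def vinfo(j):
        return parents.variants[j]

    truth_rows = []
    for j in add_qtls:
        truth_rows.append(("flowering", vinfo(j).id, vinfo(j).chrom, vinfo(j).pos, "additive", 1.2))
    truth_rows.append(("height", vinfo(dom_qtl).id, vinfo(dom_qtl).chrom, vinfo(dom_qtl).pos, "dominant", 2.0))
    truth_rows.append(("height", vinfo(epi_a).id, vinfo(epi_a).chrom, vinfo(epi_a).pos, "epistatic_masker", 0.0))
    truth_rows.append(("height", vinfo(epi_b).id, vinfo(epi_b).chrom, vinfo(epi_b).pos, "epistatic_masked", 2.2))
    for a, b in yield_pairs:
        truth_rows.append(("yield", vinfo(a).id, vinfo(a).chrom, vinfo(a).pos, "epistatic_pair", 0.6))
        truth_rows.append(("yield", vinfo(b).id, vinfo(b).chrom, vinfo(b).pos, "epistatic_pair", 0.6))
    truth = pd.DataFrame(
        truth_rows, columns=["trait", "variant", "chrom", "pos", "kind", "effect"]
    )
    return StudyBundle(parents, design, f1, traits, truth)
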