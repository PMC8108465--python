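"""Data model and file I/O shared by all pipeline stages.

Conventions used throughout the package (stated once, here):

* Genotypes are alt-allele dosages in ``{0, 1, 2}``; missing calls are
  ``NaN`` in memory and the token ``NA`` in TSV files.
* All genomic positions are 1-based and all intervals are closed, as in
  VCF.
* Variants are kept sorted by ``(chrom, pos)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridforge")

MISSING = np.nan


@dataclass(frozen=True)
class VariantInfo:
    """A single biallelic SNP.

    Parameters
    ----------
    id : str
        Variant identifier; synthesized as ``chr{c}.s_{pos}`` when the
        source provides none, matching common peak-SNP naming.
    chrom : str
    pos : int
        1-based position.
    ref, alt : str
        Alleles; must differ.
    maf : float
        Minor allele frequency in [0, 0.5], computed from non-missing
        dosages only; NaN when unknown/undefined.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.id}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages[i, j]`` is the alt-allele count of sample ``i`` at variant
    ``j`` (0, 1, 2 or NaN for missing).
    """

    sample_ids: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} dosage rows"
            )
        if m != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variants but {m} dosage columns"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            raise ValueError(
                "duplicate sample ids: "
                + ", ".join(dupes[dupes.duplicated()].unique()[:5])
            )
        if not self._is_sorted():
            logger.warning("variants not sorted by (chrom, pos); sorting")
            order = sorted(
                range(m), key=lambda j: (self.variants[j].chrom, self.variants[j].pos)
            )
            self.variants = [self.variants[j] for j in order]
            self.dosages = self.dosages[:, order]

    def _is_sorted(self) -> bool:
        keys = [(v.chrom, v.pos) for v in self.variants]
        return all(keys[j] <= keys[j + 1] for j in range(len(keys) - 1))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[str, int]:
        return {v.id: j for j, v in enumerate(self.variants)}

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return GenotypeMatrix(list(ids), list(self.variants), self.dosages[rows])

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.variants[j] for j in idx],
            self.dosages[:, idx],
        )

    def with_maf(self) -> "GenotypeMatrix":
        """Return a copy whose VariantInfo.maf fields are recomputed."""
        maf = compute_maf(self)
        variants = [
            VariantInfo(v.id, v.chrom, v.pos, v.ref, v.alt, float(maf[j]))
            for j, v in enumerate(self.variants)
        ]
        return GenotypeMatrix(list(self.sample_ids), variants, self.dosages.copy())


class TraitTable:
    """Long-format multi-environment phenotype records.

    Wraps a DataFrame with columns ``sample``, ``trait``, ``location``,
    ``year``, ``value`` (plus optional extras such as ``row`` for field
    plot order). Enforces unique (sample, trait, location, year) keys and
    finite values.
    """

    KEY = ["sample", "trait", "location", "year"]

    def __init__(self, df: pd.DataFrame):
        required = self.KEY + ["value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        # repeated check rows are legitimate when plot order is recorded
        key = self.KEY + ["row"] if "row" in df.columns else self.KEY
        if df.duplicated(key).any():
            raise ValueError(f"duplicate {tuple(key)} keys")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite trait values")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.df[self.df["trait"] == trait]

    @classmethod
    def read_tsv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF / TSV I/O
# ---------------------------------------------------------------------------

def read_vcf(path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into dosage coding.

    Dosage is the alt-allele count of the diploid GT field; ``./.`` maps
    to missing. Multiallelic records are skipped (with a logged count) or
    rejected depending on ``skip_multiallelic``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF has zero samples: {path}")
    variants: list[VariantInfo] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        vid = rec.ID or f"{rec.CHROM}.s_{rec.POS}"
        variants.append(VariantInfo(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gts012: 0/1/2 = alt count, 3 = unknown
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = MISSING
        rows.append(gt)
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, variants, dosages).with_maf()


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages back to a minimal VCF 4.2 (homozygous/het GT calls)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            gts = [
                code.get(d, "./.") if np.isfinite(d) else "./."
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_matrix(path) -> GenotypeMatrix:
    """Read the package's dosage-matrix TSV dialect.

    Header: ``id chrom pos ref alt <sample...>``; one row per variant;
    ``NA`` marks missing dosages.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    if df.columns[:5].tolist() != meta_cols:
        raise ValueError(
            f"matrix TSV must start with columns {meta_cols}, "
            f"got {df.columns[:5].tolist()}"
        )
    samples = df.columns[5:].tolist()
    variants = [
        VariantInfo(str(r.id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(samples, variants, dosages).with_maf()


def write_matrix(gm: GenotypeMatrix, path) -> None:
    meta = pd.DataFrame(
        {
            "id": [v.id for v in gm.variants],
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "ref": [v.ref for v in gm.variants],
            "alt": [v.alt for v in gm.variants],
        }
    )
    dos = pd.DataFrame(gm.dosages.T, columns=gm.sample_ids)
    out = pd.concat([meta, dos], axis=1)
    # dosages are small integers; render without trailing .0, NA for missing
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


# ---------------------------------------------------------------------------
# Basic genotype summaries
# ---------------------------------------------------------------------------

def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor allele frequency from non-missing dosages.

    maf = min(p, 1-p) with p = mean(dosage)/2; all-missing variants get
    NaN (undefined) with a warning.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(gm.dosages, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    n_undef = int(np.isnan(maf).sum())
    if n_undef:
        logger.warning("%d variants are all-missing; maf undefined", n_undef)
    return maf


def pca_scores(gm: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Principal-component scores of the centered dosage matrix.

    Missing dosages are mean-filled for this computation only. Returns a
    samples x components DataFrame (columns PC1..PCk); component
    variances are non-increasing.
    """
    from sklearn.decomposition import PCA

    if gm.n_samples < 2 or gm.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    if n_components > min(gm.n_samples, gm.n_variants):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, variants)"
        )
    X = mean_fill(gm.dosages)
    X = X - X.mean(axis=0)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    return pd.DataFrame(
        scores,
        index=gm.sample_ids,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )


def mean_fill(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (0 if all missing)."""
    import warnings

    X = np.array(dosages, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    return X
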