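"""Analysis configuration: every threshold and knob with its default."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds.

    The three GWAS significance tiers (2.2e-7 / 1e-6 / 1e-5) follow the
    genome-wide, QTL-calling and relaxed conventions of large maize NC-II
    panels; QTL grouping distances derive from an 800-kbp LD decay length
    at r^2 = 0.1.
    """

    sig_p: float = 1e-6          # QTL-calling significance tier
    suggestive_p: float = 1e-4   # peak-extension suggestive tier
    strict_p: float = 2.2e-7     # genome-wide tier (simulation two cutoff)
    fdr_p: float = 1e-5          # relaxed tier used for simulation-one FDR
    group_dist_bp: int = 800_000     # max gap between consecutive significant SNPs
    ld_r2: float = 0.1               # cross-locus LD merge threshold
    merge_dist_bp: int = 5_000_000   # max peak-to-peak distance for LD merge
    min_snps: int = 10               # significant SNPs required to emit a QTL
    ext_bp: int = 400_000            # one-shot peak extension (half LD length)
    max_extensions: int = 1
    min_subgroup: int = 30           # minimum samples per conditional-GWAS class
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sig_p", "suggestive_p", "strict_p", "fdr_p", "ld_r2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("group_dist_bp", "merge_dist_bp", "min_snps", "ext_bp"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
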