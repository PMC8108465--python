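"""QTL calling, LD merging, cross-population maps and classification."""

import numpy as np
import pandas as pd
import pytest

from hybridforge.config import AnalysisConfig
from hybridforge.qtl import (
    QTL,
    call_qtls,
    classify_heterotic_qtl,
    classify_merged_map,
    cumulative_class_effects,
    merge_across_populations,
    pairwise_r2,
)

from conftest import make_gm


# ---------------------------------------------------------------------------
# Independent brute-force oracle: transparent re-implementation of the
# grouping / merge-to-closure / emission rules on plain dicts.
# ---------------------------------------------------------------------------

def oracle_call(table, gm, cfg):
    sig = table[table["p"] <= cfg.sig_p].sort_values(["chrom", "pos"])
    recs = sig.to_dict("records")
    # seed loci: runs with consecutive gaps < group_dist_bp
    loci = []
    for r in recs:
        if (
            loci
            and loci[-1][-1]["chrom"] == r["chrom"]
            and r["pos"] - loci[-1][-1]["pos"] < cfg.group_dist_bp
        ):
            loci[-1].append(r)
        else:
            loci.append([r])

    vidx = gm.variant_index()

    def r2(va, vb):
        a, b = gm.dosages[:, vidx[va]], gm.dosages[:, vidx[vb]]
        keep = np.isfinite(a) & np.isfinite(b)
        a, b = a[keep], b[keep]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    def peak(locus):
        return sorted(locus, key=lambda r: (r["p"], r["pos"]))[0]

    def mergeable(a, b):
        if a[0]["chrom"] != b[0]["chrom"]:
            return False
        if abs(peak(a)["pos"] - peak(b)["pos"]) >= cfg.merge_dist_bp:
            return False
        return any(
            r2(x["id"], y["id"]) > cfg.ld_r2 for x in a for y in b
        )

    changed = True
    while changed:
        changed = False
        loci.sort(key=lambda l: (l[0]["chrom"], min(r["pos"] for r in l)))
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                if mergeable(loci[i], loci[j]):
                    merged = sorted(
                        loci[i] + loci[j], key=lambda r: r["pos"]
                    )
                    loci = [
                        l for k, l in enumerate(loci) if k not in (i, j)
                    ] + [merged]
                    changed = True
                    break
            if changed:
                break

    out = []
    for locus in sorted(
        loci, key=lambda l: (l[0]["chrom"], min(r["pos"] for r in l))
    ):
        chrom = locus[0]["chrom"]
        if len(locus) >= cfg.min_snps:
            out.append(
                (chrom, min(r["pos"] for r in locus),
                 max(r["pos"] for r in locus), peak(locus)["id"],
                 len(locus), "significant")
            )
        else:
            lo = min(r["pos"] for r in locus) - cfg.ext_bp
            hi = max(r["pos"] for r in locus) + cfg.ext_bp
            near = table[
                (table["chrom"] == chrom)
                & (table["pos"] >= lo)
                & (table["pos"] <= hi)
                & (table["p"] <= cfg.suggestive_p)
            ]
            if len(near) >= cfg.min_snps:
                nr = near.to_dict("records")
                out.append(
                    (chrom, min(r["pos"] for r in nr),
                     max(r["pos"] for r in nr), peak(nr)["id"],
                     len(nr), "suggestive")
                )
    return out


def random_fixture(seed, n_snps=80, n_samples=40):
    rng = np.random.default_rng(seed)
    from hybridforge.simulate import gen_inbred_genotypes

    gm = gen_inbred_genotypes(
        n_samples, n_snps, seed=seed, ld_block_len=8, block_rho=0.9,
        n_chrom=3, spacing_bp=int(rng.integers(100_000, 600_000)),
    )
    # p-values: mixture of null and strong signals in random stretches
    p = 10.0 ** rng.uniform(-3, 0, size=n_snps)
    for _ in range(rng.integers(1, 4)):
        c = rng.integers(0, n_snps)
        w = rng.integers(3, 15)
        lo, hi = max(0, c - w), min(n_snps, c + w)
        p[lo:hi] = 10.0 ** rng.uniform(-12, -4, size=hi - lo)
    table = pd.DataFrame(
        {
            "id": [v.id for v in gm.variants],
            "chrom": [v.chrom for v in gm.variants],
            "pos": [v.pos for v in gm.variants],
            "p": p,
        }
    )
    return table, gm


class TestPairwiseR2:
    def test_identical_vectors(self):
        gm = make_gm([[0, 0], [1, 1], [2, 2], [0, 0]])
        assert pairwise_r2(gm, gm.variants[0].id, gm.variants[1].id) == 1.0

    def test_orthogonal_vectors(self):
        gm = make_gm([[0, 0], [0, 2], [2, 0], [2, 2]])
        assert pairwise_r2(gm, gm.variants[0].id, gm.variants[1].id) == 0.0

    def test_matches_covariance_formula(self, rng):
        a = rng.choice([0.0, 1.0, 2.0], 200)
        b = rng.choice([0.0, 1.0, 2.0], 200)
        gm = make_gm(np.column_stack([a, b]))
        got = pairwise_r2(gm, gm.variants[0].id, gm.variants[1].id)
        cov = np.mean(a * b) - a.mean() * b.mean()
        expect = cov**2 / (np.var(a) * np.var(b))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_treated_as_zero(self):
        gm = make_gm([[2, 0], [2, 2], [2, 0]])
        assert pairwise_r2(gm, gm.variants[0].id, gm.variants[1].id) == 0.0


class TestCallQtls:
    def test_no_significant_snps_gives_empty_list(self, small_panel):
        table = pd.DataFrame(
            {
                "id": [v.id for v in small_panel.variants],
                "chrom": [v.chrom for v in small_panel.variants],
                "pos": [v.pos for v in small_panel.variants],
                "p": 0.5,
            }
        )
        assert call_qtls(table, small_panel) == []

    def test_ld_merge_of_two_small_loci(self):
        # two 6-SNP loci 2 Mbp apart, one cross pair in strong LD
        n = 12
        base = np.tile([0.0, 0, 2, 2, 0, 2, 0, 2, 2, 0], (n, 1)).T[:10]
        D = np.zeros((10, 12))
        for j in range(12):
            D[:, j] = base[:, 0] if j in (5, 6) else np.roll(base[:, 0], j)
        pos = [100_000 * (j + 1) for j in range(6)] + [
            2_600_000 + 100_000 * j for j in range(6)
        ]
        gm = make_gm(D, positions=pos)
        table = pd.DataFrame(
            {
                "id": [v.id for v in gm.variants],
                "chrom": "chr01",
                "pos": pos,
                "p": 1e-8,
            }
        )
        cfg = AnalysisConfig(min_snps=10)
        qtls = call_qtls(table, gm, cfg)
        assert len(qtls) == 1
        assert qtls[0].n_sig_snps == 12
        assert qtls[0].support == "significant"

    def test_distant_unlinked_loci_stay_separate(self, rng):
        D = rng.choice([0.0, 2.0], size=(30, 24))
        pos = [100_000 * (j + 1) for j in range(12)] + [
            20_000_000 + 100_000 * j for j in range(12)
        ]
        gm = make_gm(D, positions=pos)
        table = pd.DataFrame(
            {
                "id": [v.id for v in gm.variants],
                "chrom": "chr01",
                "pos": pos,
                "p": 1e-9,
            }
        )
        qtls = call_qtls(table, gm, AnalysisConfig(min_snps=10))
        assert len(qtls) == 2

    def test_small_locus_rescued_by_extension(self):
        D = np.tile(
            np.array([[0.0], [0], [2], [2], [0], [2], [0], [2], [2], [0]]),
            (1, 12),
        )
        pos = [70_000 * (j + 1) for j in range(12)]
        gm = make_gm(D, positions=pos)
        p = np.full(12, 1e-5)  # suggestive only
        p[5] = 1e-8            # single significant SNP
        table = pd.DataFrame(
            {"id": [v.id for v in gm.variants], "chrom": "chr01",
             "pos": pos, "p": p}
        )
        qtls = call_qtls(table, gm, AnalysisConfig(min_snps=10))
        assert len(qtls) == 1
        assert qtls[0].support == "suggestive"
        assert qtls[0].peak_pos == pos[5]

    def test_peak_inside_interval_and_minimal(self, rng):
        for seed in range(10):
            table, gm = random_fixture(seed + 500)
            for q in call_qtls(table, gm, AnalysisConfig(min_snps=4)):
                assert q.start <= q.peak_pos <= q.end
                inside = table[
                    (table["chrom"] == q.chrom)
                    & (table["pos"] >= q.start)
                    & (table["pos"] <= q.end)
                    & (table["p"] <= 1e-6)
                ]
                if len(inside):
                    assert q.peak_p <= inside["p"].min() + 1e-300

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        cfg = AnalysisConfig(min_snps=4)
        table, gm = random_fixture(seed)
        got = [
            (q.chrom, q.start, q.end, q.peak_id, q.n_sig_snps, q.support)
            for q in call_qtls(table, gm, cfg)
        ]
        assert got == oracle_call(table, gm, cfg)


class TestMergeAcrossPopulations:
    def _q(self, start, end, pop="p1", chrom="chr01", peak=None):
        peak = peak if peak is not None else start
        return QTL(chrom, start, end, f"v{start}", peak, 1e-8, 10,
                   "significant", pop, "t")

    def test_overlapping_intervals_merge(self):
        merged = merge_across_populations(
            [[self._q(100, 200, "p1")], [self._q(150, 300, "p2")]]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 300)
        assert merged[0].populations == ["p1", "p2"]

    def test_disjoint_intervals_stay_apart(self):
        merged = merge_across_populations(
            [[self._q(1, 10)], [self._q(20, 30)]]
        )
        assert len(merged) == 2

    def test_transitive_chain_collapses(self):
        # a&b overlap, b&c overlap, a&c do not
        merged = merge_across_populations(
            [[self._q(1, 100)], [self._q(90, 200)], [self._q(190, 300)]]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (1, 300)


class TestClassifier:
    TRUTH = {
        (1, 1, 0): "additive",
        (1, 1, 1): "additive",
        (1, 0, 1): "dominant",
        (1, 0, 0): "unclassified",
        (0, 1, 0): "epistatic_DxA",
        (0, 1, 1): "epistatic_DxA",
        (0, 0, 1): "epistatic_DxD",
        (0, 0, 0): "unclassified",
    }

    @pytest.mark.parametrize("pattern", list(TRUTH))
    def test_full_truth_table(self, pattern):
        cls = classify_heterotic_qtl(*pattern)
        assert cls.label == self.TRUTH[pattern]

    def test_ambiguous_and_flagged_cells(self):
        assert classify_heterotic_qtl(1, 1, 1).flag == "with-dominance"
        assert classify_heterotic_qtl(0, 1, 1).flag == "subtype-ambiguous"

    def test_classified_map_sources(self):
        m = [QTL("chr01", 100, 200, "a", 150, 1e-9, 12, "significant", "maternal", "t")]
        f = [QTL("chr01", 150, 250, "b", 160, 1e-8, 11, "significant", "T1", "t")]
        d = [QTL("chr02", 100, 200, "c", 150, 1e-7, 10, "significant", "T1", "MPH.t")]
        out = classify_merged_map(m, f, d)
        assert out.loc[0, "class"] == "additive"
        assert out.loc[1, "class"] == "epistatic_DxD"


class TestCumulativeEffects:
    @staticmethod
    def _q(i, pop, beta_id):
        start = 1000 + i * 10_000_000
        return QTL("chr01", start, start + 100, beta_id, start, 1e-9, 10,
                   "significant", pop, "t")

    def test_hand_summed_totals(self):
        import types

        # two additive QTLs (|beta| 0.3, 0.2; each seen in maternal + F1)
        # and one epistatic QTL (|beta| 0.4; F1-only)
        m_qtls = [self._q(0, "maternal", "v0"), self._q(1, "maternal", "v1")]
        f_qtls = [self._q(0, "f1pop", "v0"), self._q(1, "f1pop", "v1"),
                  self._q(2, "f1pop", "v2")]
        tab = pd.DataFrame(
            {"id": ["v0", "v1", "v2"], "chrom": "chr01",
             "pos": [1000, 10_001_000, 20_001_000],
             "beta": [0.3, 0.2, 0.4], "se": 0.1, "p": 1e-9}
        )
        results = {
            ("maternal", "t"): types.SimpleNamespace(table=tab),
            ("f1pop", "t"): types.SimpleNamespace(table=tab),
        }
        classified = classify_merged_map(m_qtls, f_qtls, [])
        from hybridforge.qtl import merge_across_populations

        merged = merge_across_populations([m_qtls + f_qtls])
        out = cumulative_class_effects(classified, merged, results)
        totals = dict(zip(out["class"], out["cumulative_abs_beta"]))
        assert totals["additive"] == pytest.approx(0.5)
        assert totals["epistatic"] == pytest.approx(0.4)

    def test_empty_map_gives_empty_table(self):
        out = cumulative_class_effects(
            pd.DataFrame(columns=["class"]), [], {}
        )
        assert len(out) == 0
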